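# Methods

## Problem setting and model

The package classifies volumetric retinal OCT into diabetic retinopathy
(DR = 0) versus diabetic nephropathy (DN = 1, the positive class), using
a 3D residual CNN whose attention is guided toward lesion-prone regions.
Training is two-staged: the plain backbone is trained first; Grad-CAM
applied to that model yields one binary lesion mask per eye; a
mask-guided self-attention module is then inserted into the backbone and
the combined network is retrained.  The premise is that the class
evidence (hyperreflective macular lesions) occupies a small part of each
volume, and that an explicit spatial prior — even a rough, self-derived
one — helps a small-sample classifier attend to it.

## Preprocessing

Inputs are per-eye stacks of 400 grayscale B-scans, 400x640 px.  The
chain per eye: keep slices [130, 270) — a half-open window, so exactly
140 slices, matching the stated count (an inclusive reading would give
141) — subsample at stride 2 to 70; crop the middle 140 columns of each
slice; binarize; dilate; keep the largest connected component's filled
region and zero the rest; resize to 100x100 bilinearly; divide by 255 and
stack to a 100x100x70 volume.  Indexing is 0-based ("130th" maps to
index 130).

Choices the procedure leaves open, fixed here as defaults:

- **Binarization threshold**: Otsu, falling back to a fixed threshold of
  25 (logged) on constant slices.  Otsu adapts to the phantom's and any
  clinical export's intensity scale.
- **Dilation**: 5-px elliptical (disk) element, 2 iterations.  Enough to
  bridge gaps between retinal bands so the foreground is one component.
- **Resize**: bilinear on the masked grayscale slice, no aspect
  preservation, no anti-aliasing — the simplest reading of
  "standardized to 100x100x70".
- Foreground is not tightened to its bounding box before resizing; the
  full 140x640 masked slice is resized.

No randomness exists anywhere in this module.

## Grad-CAM and mask generation

Channel weights are the class-score gradients w.r.t. the tap layer's
activations, global-average-pooled over all three spatial axes (the 2D
formulation pools over width and height; with a 3D backbone the only
consistent extension pools depth too, and Z is the product of the three
extents).  The map is the ReLU of the alpha-weighted activation sum,
taken at the last residual stage by default (configurable).  One 3D map
is computed per volume, not one 2D map per slice — the model is 3D.

Binarization: the map is min-max normalized to [0, 255], upsampled
trilinearly to volume resolution and thresholded at T = 50, with values
exactly equal to T mapping to 1 (the threshold rule as printed; its
surrounding prose says "greater than", and the printed formula wins).
The normalized map is thresholded directly rather than re-rendering it
through a color map and taking the R channel: the color-map detour adds
an arbitrary nonlinearity the method does not depend on.  A constant map
(no localization signal) falls back to an all-ones mask, so the attention
module degrades to plain self-attention instead of zeroing features.

Mask policy: true labels drive mask generation at training time,
predicted labels at inference (test labels are unavailable in
deployment).  Masks are cached keyed on (model checksum, eye, threshold,
policy, layer).

## Attention module

With site features X reshaped to C x N (N = D·H·W positions) and the
mask resampled to the site's grid (nearest neighbor, so it stays binary):
X_L = X ⊙ X_B, X_LC = conv1x1x1(X_L) (query and key), X_C = conv1x1x1(X)
(value), and A_L = softmax(X_LC^T X_LC) X_C + X_C with a rowwise softmax
(each query position attends over all positions).  Both convolutions
preserve the channel count so A_L replaces X.

Interpretation decisions, recorded because the update rule's bracketing
is ambiguous as written:

- The literal reading softmax(X_LC X_LC^T X_C) applies the softmax after
  the value product; it is dimensionally awkward for an attention
  distribution over positions.  The default is the standard attention
  reading (scores, softmax, then value); the literal one is implemented
  behind `bracketing: literal`.  Both have exact hand-written gradients,
  checked against central differences.
- The residual is "+ X_C" as printed — the value projection of X, not X
  itself; information loss from masking is avoided because X_C sees the
  unmasked features.
- No 1/sqrt(d) attention scaling by default (the rule has none); a flag
  enables it.
- X_B is the raw binary mask, not a feature-extracted one.
- Default insertion is one module per residual stage (4 sites); memory in
  the N x N attention matrix grows quickly with per-block insertion,
  which remains available (`insertion: per_block`, 8 sites on ResNet-18)
  and is the literal "after each residual block".

## Backbone

Standard 3D-ResNet recipe: 7x7x7 stride-2 stem + 3x3x3 stride-2 max
pool, four stages (basic blocks for depths 18/34, bottlenecks for
50/101), global average pooling, linear head.  The depth axis is strided
like H and W at every downsampling (70 input slices tolerate the four
halvings); `downsample_depth: false` keeps depth resolution.  Kaiming
fan-out initialization; no pretrained weights exist for this input
geometry.  All layers are numpy with explicit backward passes; every
layer and both attention bracketings are verified against
central-difference gradients at 1e-7 in the tests.

## Training

Stage 1 and stage 2 both use Adam (lr 1e-4), cross-entropy, StepLR, 150
epochs, batch 2.  StepLR's step/gamma are unstated upstream: defaults 50
and 0.1.  Augmentation is an in-plane rotation uniform in ±10° and an
isotropic in-plane scale uniform in [0.9, 1.1] — ranges unstated
upstream, chosen as mild, anatomy-preserving defaults — one draw per
volume, applied identically to every slice, and in stage 2 also to the
mask (nearest neighbor) so the attended region moves with the anatomy.
Volumes are min-max normalized per volume before batching.

Stage 2 generates masks once from the frozen stage-1 model and keeps them
fixed (the framework draws a single mask-generation step; per-epoch
refreshing is deliberately not the default).  The attention network's
backbone warm-starts from stage 1 and the attention parameters are fresh;
`warm_start: false` trains from scratch.  Given a seed, a full two-stage
run is bit-for-bit reproducible on one device.

## Evaluation

Patient-level 5-fold cross-validation: the splitting unit is the patient
(all eyes of a patient share a fold) to prevent identity leakage.  Per-eye
DN probabilities are averaged into one score per patient — one clinical
decision per patient; the aggregation rule is otherwise unspecified
upstream.  Metrics are accuracy, sensitivity and specificity with DN
positive; a zero denominator yields NaN and that fold is excluded from
the mean with a warning.  ROC is a threshold sweep over the pooled
patient scores and AUC is trapezoidal (scikit-learn).

## Phantom generator

Each synthetic eye is a stack of B-scans: a dark background (intensity
~10), `n_layers` smooth bright bands (intensity 150–235) whose centers
follow low-order polynomials in the column coordinate with a slow
modulation along the stack, Gaussian intensity noise (sigma 8 by
default), and optionally a hyperreflective spherical lesion (intensity
245).  DN eyes receive a lesion inside the central slice window and
central columns — the region the macular crop retains — with radius
1.0–1.4x the base radius; DR eyes receive a smaller peripheral blob that
the crop removes.  The label is therefore carried exactly by content that
survives preprocessing.  Identical specs (including seed) produce
bit-identical stacks; per-slice noise streams derive from
(seed, slice index) so slices can be generated independently.

What the phantom does *not* emulate: OCT speckle statistics, vasculature,
pathology heterogeneity, acquisition artifacts, or inter-patient
anatomical variability beyond band-shape jitter.  Tests passing on
phantoms therefore demonstrate the pipeline's mechanics (shapes,
gradients, mask guidance, reproducibility, the relative benefit of
attention when the class signal is spatially localized) — not clinical
performance.

## Reduced problem sizes

The comparison experiment (`octlam.experiments`) runs at sizes a single
CPU handles comfortably: 20 patients (50% DN), stacks of 64 slices at
120x160 px, volumes of 48x48x16 (slice window [16, 48), stride 2, crop
60), ResNet-18 with 8 base channels, 20 epochs at lr 1e-3 (StepLR 10 /
0.1), 30% of patients held out, three seeds, and the median held-out
accuracy of the two-stage attention model compared against the stage-1
baseline.  These values are the package's fixed desk-scale study
conditions, chosen once; the clinical-scale defaults remain the
module-level defaults everywhere.

## Known limitations

- The numpy network is CPU-bound; clinical-scale 100x100x70 training at
  depth 101 is possible but slow.  The implementation favors exactness
  and testability over throughput.
- Per-block insertion at early stages forms large N x N attention
  matrices (N = 4608 after the stem at full resolution).
- Batch norm with batch size 2 is noisy; running statistics still
  converge in practice, and evaluation always uses them.
- The constant-map mask fallback (all ones) makes stage 2 no worse than
  plain self-attention but cannot help localization for that eye.
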