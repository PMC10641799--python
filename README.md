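# octlam

Lesion-aware attention network for volumetric retinal-OCT classification.

Diabetic nephropathy (DN) and diabetic retinopathy (DR) are both
microvascular complications of diabetes, and retinal optical coherence
tomography (OCT) carries signal about which of the two a patient has —
but the discriminative lesions occupy a small part of each scan, which
plain CNN classifiers handle poorly.  `octlam` implements a two-stage
remedy: train a 3D residual CNN on preprocessed OCT volumes, use Grad-CAM
to turn the trained model's own class evidence into a rough binary lesion
mask per eye, then insert a mask-guided self-attention module into the
CNN and retrain, so the network is explicitly steered toward lesion-prone
regions.  The package is aimed at researchers who want to study this
attention-guided training scheme end to end without access to clinical
data: a phantom module synthesizes layered, B-scan-like stacks whose class
label is carried by a central hyperreflective lesion.

## Method

Each eye's stack of 400 B-scans (400x640 px) is reduced to a volume:
slices [130, 270) are kept (140), subsampled at stride 2 (70), each slice
is cropped to its middle 140 columns, binarized (Otsu), dilated, reduced
to the largest connected foreground component, resized to 100x100 and
stacked into a 100x100x70 volume in [0, 1].

**Grad-CAM.** For class score `y^c` and tap-layer activations `A^k`, the
channel weights are the spatially pooled gradients

    alpha_k^c = (1/Z) * sum_{i,j,l} dy^c / dA^k_{ijl},      Z = D*H*W

and the localization map is `L^c = ReLU(sum_k alpha_k^c A^k)`.  `L^c` is
min-max scaled to [0, 255], upsampled to volume resolution, and
binarized at threshold `T = 50` (values >= T map to 1).

**Lesion-aware attention (LAM).** At an insertion site with features `X`
(N positions after flattening D, H, W), the mask `X_B` is resampled to
the site's grid and

    X_L  = X .* X_B                (lesion-related features)
    X_LC = conv1x1x1(X_L)          (query = key)
    X_C  = conv1x1x1(X)            (value)
    A_L  = softmax(X_LC^T X_LC) X_C + X_C

with a rowwise softmax over positions.  `A_L` replaces `X` in the
backbone; one module is inserted after each residual stage (after each
block with `insertion: per_block`).

**Training.** Stage 1: plain 3D ResNet (depths 18/34/50/101), Adam at
1e-4, StepLR, cross-entropy, 150 epochs, batch 2, random in-plane
rotation/scaling.  Stage 2: masks are generated once from the frozen
stage-1 model (true-label policy), then the attention network trains with
the backbone warm-started from stage 1.  Evaluation is patient-level
5-fold cross-validation with accuracy, sensitivity and specificity
(DN positive), pooled ROC and trapezoidal AUC.

The network layers (3D convolution, batch norm, pooling, attention) are
implemented in numpy with hand-written backpropagation; every layer is
verified against central-difference gradients in the test suite.

## Worked example

Synthesize ten phantom patients at a reduced geometry, preprocess, train
both stages and cross-validate (about two minutes on one CPU):

```bash
octlam phantom    --n 10 --dn-fraction 0.5 --seed 7 --config cfg.yaml --out raw/
octlam preprocess --data raw/ --config cfg.yaml --out vols/
octlam train      --stage all --data vols/volumes.tsv --config cfg.yaml --seed 7 --out run/
octlam evaluate   --data vols/volumes.tsv --config cfg.yaml --model lam --k 5 --seed 7 --out report.json
```

with `cfg.yaml` holding the reduced sizes (48x48x16 volumes, ResNet-18
with 8 base channels, 12 epochs; see `docs/methods.md`).  The run prints

```
stage 1 final train accuracy 1.000
stage 2 final train accuracy 1.000
{
  "accuracy": 1.0,
  "sensitivity": 1.0,
  "specificity": 1.0
}
```

The stage accuracies show both the baseline and the attention network fit
the training patients; the JSON block is the cross-validated mean over the
five test folds — on these cleanly separable phantoms the attention model
classifies every held-out patient correctly (pooled AUC 1.0).  `octlam
ablate` repeats the comparison over backbone depths, writing one
cross-validation report per (depth, baseline/attention) cell.

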