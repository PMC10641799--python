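"""Desk-scale experiments on phantom data.

The main experiment compares the plain backbone (stage 1) with the
two-stage attention network on a seeded phantom dataset, at a reduced
problem size a single CPU handles: 20 patients, 48x48x16 volumes, a
narrow ResNet-18 and 20 epochs.  It mirrors the ablation structure of the
full-scale study (every attention-augmented model compared to its
baseline) on data whose class signal lives, by construction, in the
central region the lesion masks highlight.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from . import cam as cam_mod
from .backbone import BackboneConfig
from .lam import LamConfig
from .phantom import PhantomSpec, generate_dataset
from .preprocess import PreprocessConfig, Volume, assemble_volume
from .train import TrainConfig, predict_proba, train_stage1, train_stage2

log = logging.getLogger(__name__)

# reduced-geometry study conditions (see docs/methods.md)
SMALL_PHANTOM = PhantomSpec(
    width=120, height=160, n_slices=64, n_layers=4,
    lesion_radius=7.0, noise_sigma=8.0,
)
SMALL_PREPROCESS = PreprocessConfig(
    slice_lo=16, slice_hi=48, sample_stride=2, crop_width=60,
    out_xy=48, out_depth=16,
)
SMALL_BACKBONE = BackboneConfig(depth=18, base_channels=8)
SMALL_TRAIN = TrainConfig(epochs=20, batch_size=2, lr=1e-3, step_size=10, gamma=0.1)


@dataclass
class AdvantageResult:
    per_seed: list[dict]
    baseline_median: float
    lam_median: float

    @property
    def advantage(self) -> float:
        return self.lam_median - self.baseline_median


def make_small_dataset(n_patients: int = 20, dn_fraction: float = 0.5, seed: int = 0) -> list[Volume]:
    """Phantom volumes at the reduced 48x48x16 geometry."""
    stacks = generate_dataset(n_patients, dn_fraction, SMALL_PHANTOM, seed=seed)
    return [assemble_volume(s, SMALL_PREPROCESS) for s in stacks]


def holdout_split(volumes: list[Volume], test_fraction: float = 0.3, seed: int = 0):
    """Patient-level holdout split."""
    patients = sorted({v.patient_id for v in volumes})
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 40]))
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_test = max(1, int(round(len(patients) * test_fraction)))
    test = set(order[:n_test])
    return ([v for v in volumes if v.patient_id not in test],
            [v for v in volumes if v.patient_id in test])


def _holdout_accuracy(model, test_set, masks=None) -> float:
    proba = predict_proba(model, test_set, masks)
    pred = proba.argmax(axis=1)
    truth = np.array([v.label for v in test_set])
    return float((pred == truth).mean())


def lam_advantage_experiment(
    seeds=(0, 1, 2),
    n_patients: int = 20,
    dn_fraction: float = 0.5,
    backbone_cfg: BackboneConfig = SMALL_BACKBONE,
    lam_cfg: LamConfig = LamConfig(),
    train_cfg: TrainConfig = SMALL_TRAIN,
) -> AdvantageResult:
    """Held-out accuracy of stage-1 baseline vs the two-stage attention model.

    Each seed regenerates the dataset, resplits patients, and trains both
    models; the comparison is between the medians over seeds.
    """
    per_seed = []
    for seed in seeds:
        data = make_small_dataset(n_patients, dn_fraction, seed=seed)
        train_set, test_set = holdout_split(data, seed=seed)
        labels = [v.label for v in train_set]
        cfg = dataclasses.replace(train_cfg, seed=seed)
        s1 = train_stage1(train_set, labels, backbone_cfg, cfg)
        base_acc = _holdout_accuracy(s1.model, test_set)
        s2 = train_stage2(train_set, labels, s1, lam_cfg, cfg)
        test_masks = cam_mod.batch_generate_masks(
            s1.model, test_set, label_policy="predicted",
            threshold=cfg.mask_threshold, layer_name=cfg.mask_layer,
        )
        lam_acc = _holdout_accuracy(s2.model, test_set, masks=test_masks)
        log.info("seed %d: baseline %.3f lam %.3f", seed, base_acc, lam_acc)
        per_seed.append({"seed": seed, "baseline_accuracy": base_acc, "lam_accuracy": lam_acc})
    return AdvantageResult(
        per_seed=per_seed,
        baseline_median=float(np.median([r["baseline_accuracy"] for r in per_seed])),
        lam_median=float(np.median([r["lam_accuracy"] for r in per_seed])),
    )
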