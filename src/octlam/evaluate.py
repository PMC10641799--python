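"""Metrics, patient-level 5-fold cross-validation and ROC/AUC reporting.

The positive class is DN throughout.  Accuracy, sensitivity and
specificity are the usual confusion-table ratios; a zero denominator
yields NaN rather than an exception.  Cross-validation splits at the
patient level (all volumes of one patient share a fold, preventing
identity leakage), per-eye DN probabilities are averaged to one score
per patient, and the pooled ROC/AUC uses the trapezoidal rule via
scikit-learn.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .backbone import BackboneConfig
from .lam import LamConfig
from .phantom import DN
from .preprocess import Volume
from .train import TrainConfig, config_hash, predict_proba, train_stage1, train_stage2

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where the denominator is 0."""
    n = counts.n
    acc = (counts.tp + counts.tn) / n if n else math.nan
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    return acc, sens, spec


def counts_from_predictions(y_true, y_pred, positive=DN) -> ConfusionCounts:
    y_true = np.asarray(y_true) == positive
    y_pred = np.asarray(y_pred) == positive
    return ConfusionCounts(
        tp=int((y_true & y_pred).sum()),
        fp=int((~y_true & y_pred).sum()),
        tn=int((~y_true & ~y_pred).sum()),
        fn=int((y_true & ~y_pred).sum()),
    )


@dataclass
class FoldSplit:
    fold_id: int
    train_patient_ids: list[str]
    test_patient_ids: list[str]


def make_folds(patient_ids, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Shuffle patients and partition into k near-equal test groups."""
    patients = sorted(set(patient_ids))
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, got {len(patients)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 30]))
    order = [patients[i] for i in rng.permutation(len(patients))]
    groups = np.array_split(order, k)
    folds = []
    for i, g in enumerate(groups, start=1):
        test = sorted(str(p) for p in g)
        train = sorted(p for p in patients if p not in set(test))
        folds.append(FoldSplit(fold_id=i, train_patient_ids=train, test_patient_ids=test))
    return folds


def roc_auc(y_true, scores, positive=DN) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (threshold sweep over the scores) and trapezoidal AUC."""
    fpr, tpr, _ = _sk_roc_curve(np.asarray(y_true) == positive, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def _patient_scores(volumes, proba) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Average the DN probability over a patient's eyes; one score each."""
    by_patient: dict[str, list[int]] = {}
    for i, v in enumerate(volumes):
        by_patient.setdefault(v.patient_id, []).append(i)
    pids = sorted(by_patient)
    scores = np.array([proba[by_patient[p], DN].mean() for p in pids])
    labels = np.array([volumes[by_patient[p][0]].label for p in pids])
    return pids, scores, labels


def crossvalidate(
    volumes: list[Volume],
    backbone_cfg: BackboneConfig = BackboneConfig(),
    lam_cfg: LamConfig | None = None,
    train_cfg: TrainConfig = TrainConfig(),
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Patient-level k-fold CV of the one-stage (lam_cfg=None) or two-stage model.

    Returns a JSON-serializable report with per-fold and mean metrics,
    fold memberships, the pooled ROC and its AUC.
    """
    folds = make_folds([v.patient_id for v in volumes], k=k, seed=seed)
    fold_reports = []
    pooled_scores, pooled_labels = [], []
    for fold in folds:
        train_set = [v for v in volumes if v.patient_id in set(fold.train_patient_ids)]
        test_set = [v for v in volumes if v.patient_id in set(fold.test_patient_ids)]
        labels = [v.label for v in train_set]
        import dataclasses as _dc

        fold_cfg = _dc.replace(train_cfg, seed=train_cfg.seed + fold.fold_id)
        s1 = train_stage1(train_set, labels, backbone_cfg, fold_cfg)
        if lam_cfg is None:
            model = s1.model
            proba = predict_proba(model, test_set)
        else:
            s2 = train_stage2(train_set, labels, s1, lam_cfg, fold_cfg)
            model = s2.model
            # inference masks from the stage-1 model under the predicted class
            from . import cam as cam_mod

            masks = cam_mod.batch_generate_masks(
                s1.model, test_set, label_policy="predicted",
                threshold=fold_cfg.mask_threshold, layer_name=fold_cfg.mask_layer,
            )
            proba = predict_proba(model, test_set, masks)
        pids, scores, ptruth = _patient_scores(test_set, proba)
        pred = (scores >= 0.5).astype(int)
        counts = counts_from_predictions(ptruth, pred)
        acc, sens, spec = metrics(counts)
        if math.isnan(sens) or math.isnan(spec):
            log.warning("fold %d test set is single-class; its undefined metric is "
                        "excluded from the mean", fold.fold_id)
        fold_reports.append({
            "fold_id": fold.fold_id,
            "test_patients": pids,
            "counts": asdict(counts),
            "accuracy": acc, "sensitivity": sens, "specificity": spec,
        })
        pooled_scores.extend(scores.tolist())
        pooled_labels.extend(ptruth.tolist())
    def _nanmean(key):
        vals = [f[key] for f in fold_reports if not math.isnan(f[key])]
        return float(np.mean(vals)) if vals else math.nan
    fpr, tpr, aucv = roc_auc(pooled_labels, pooled_scores)
    return {
        "k": k,
        "seed": seed,
        "config_hash": config_hash(backbone_cfg, lam_cfg, train_cfg),
        "folds": fold_reports,
        "fold_memberships": {f.fold_id: f.test_patient_ids for f in folds},
        "mean": {
            "accuracy": _nanmean("accuracy"),
            "sensitivity": _nanmean("sensitivity"),
            "specificity": _nanmean("specificity"),
        },
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "auc": aucv,
    }


def save_report(report: dict, path, roc_plot=None) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=float)
    if roc_plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(report["roc"]["fpr"], report["roc"]["tpr"], label=f"AUC = {report['auc']:.3f}")
        ax.plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(roc_plot, dpi=120)
        plt.close(fig)
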