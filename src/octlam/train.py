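"""Two-stage training: baseline backbone first, then the attention network.

Stage 1 trains the plain 3D ResNet with Adam, cross-entropy and a StepLR
schedule.  Stage 2 generates one Grad-CAM lesion mask per volume from the
frozen stage-1 model (a single pass; masks are not refreshed during
training), builds the attention network, warm-starts its backbone from the
stage-1 weights, and trains end to end with the mask fed alongside each
volume.  Augmentation is an in-plane rotation (uniform in +-rotate_deg)
and isotropic in-plane scaling (uniform in [scale_lo, scale_hi]); one draw
per volume, shared by the volume and its mask so the masked region moves
with the anatomy.  Everything is reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from . import cam as cam_mod
from .backbone import (
    BackboneConfig,
    ResNet3D,
    backbone_config_dict,
    backbone_config_from_dict,
    load_checkpoint,
    save_checkpoint,
)
from .lam import LamConfig, LamNetwork
from .nn import Adam, StepLR, cross_entropy, softmax
from .preprocess import Volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 2
    lr: float = 1e-4
    step_size: int = 50
    gamma: float = 0.1
    augment: bool = True
    rotate_deg: float = 10.0
    scale_lo: float = 0.9
    scale_hi: float = 1.1
    mask_threshold: float = 50.0
    mask_layer: str = "stage4"
    warm_start: bool = True  # stage 2 reuses stage-1 backbone weights
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")


@dataclass
class StageResult:
    checkpoint: Path | None
    loss_curve: list[float]
    lr_curve: list[float]
    final_train_accuracy: float
    seed: int
    config_hash: str
    model: object = field(repr=False, default=None)


def config_hash(*cfgs) -> str:
    payload = json.dumps([asdict(c) if hasattr(c, "__dataclass_fields__") else c for c in cfgs],
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _normalize(data: np.ndarray) -> np.ndarray:
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def augment_volume(
    data: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
):
    """Shared in-plane rotation + scaling for a (H, W, D) volume and mask.

    Depth order is anatomical, so only the B-scan plane is transformed.
    Returns the transformed volume (clipped to [0, 1]) and, if given, the
    mask warped with the identical transform (nearest neighbor).
    """
    angle = rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)
    scale = rng.uniform(cfg.scale_lo, cfg.scale_hi)
    if angle == 0.0 and scale == 1.0:
        return (data, mask) if mask is not None else (data, None)
    th = np.deg2rad(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) / scale
    minv = np.eye(3)
    minv[:2, :2] = rot  # output -> input coordinates, identity on depth
    center = np.array([(data.shape[0] - 1) / 2.0, (data.shape[1] - 1) / 2.0, 0.0])
    offset = center - minv @ center
    out = ndi.affine_transform(data, minv, offset=offset, order=1, mode="constant", cval=0.0)
    out = np.clip(out, 0.0, 1.0)
    if mask is None:
        return out, None
    wm = ndi.affine_transform(
        mask.astype(np.float64), minv, offset=offset, order=0, mode="constant", cval=0.0
    )
    return out, wm


def _to_batch(volumes: list[np.ndarray]) -> np.ndarray:
    return np.stack([np.moveaxis(v, -1, 0)[None] for v in volumes])


def _predict_scores(model, volumes: list[Volume], masks=None) -> np.ndarray:
    scores = []
    for v in volumes:
        x = _to_batch([_normalize(v.data)])
        if masks is None:
            s = model.forward(x, train=False)
        else:
            m = np.moveaxis(masks[(v.patient_id, v.eye_id)].values, -1, 0)
            s = model.forward(x, mask=m[None], train=False)
        scores.append(s[0])
    return np.asarray(scores)


def predict_proba(model, volumes: list[Volume], masks=None) -> np.ndarray:
    """Softmax class probabilities, one row per volume."""
    return softmax(_predict_scores(model, volumes, masks), axis=1)


def _check_two_classes(labels):
    if len(set(int(l) for l in labels)) < 2:
        raise ValueError("training labels contain a single class; need both DR and DN")


def _train_loop(model, volumes, labels, cfg: TrainConfig, masks=None):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 11]))
    opt = Adam(model.parameters(), lr=cfg.lr)
    sched = StepLR(opt, cfg.step_size, cfg.gamma)
    n = len(volumes)
    losses, lrs = [], []
    normed = [_normalize(v.data) for v in volumes]
    mask_arrs = None
    if masks is not None:
        mask_arrs = [masks[(v.patient_id, v.eye_id)].values for v in volumes]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xs, ms = [], []
            for i in idx:
                d = normed[i]
                mk = mask_arrs[i] if mask_arrs is not None else None
                if cfg.augment:
                    d, mk = augment_volume(d, cfg, rng, mk)
                xs.append(d)
                if mk is not None:
                    ms.append(np.moveaxis(mk, -1, 0))
            x = _to_batch(xs)
            y = np.asarray([labels[i] for i in idx], dtype=np.intp)
            if mask_arrs is not None:
                out = model.forward(x, mask=np.stack(ms), train=True)
            else:
                out = model.forward(x, train=True)
            loss, dl = cross_entropy(out, y)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.zero_grad()
            model.backward(dl)
            opt.step()
            epoch_loss += loss
            nb += 1
        sched.step()
        losses.append(epoch_loss / max(nb, 1))
        lrs.append(sched.lr)
        log.info("epoch %d loss %.4f lr %.2e", epoch, losses[-1], lrs[-1])
    return losses, lrs


def _train_accuracy(model, volumes, labels, masks=None) -> float:
    proba = predict_proba(model, volumes, masks)
    pred = proba.argmax(axis=1)
    return float((pred == np.asarray(labels)).mean())


def train_stage1(
    volumes: list[Volume],
    labels: list[int],
    backbone_cfg: BackboneConfig = BackboneConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    out_dir=None,
) -> StageResult:
    """Train the plain backbone; returns the result with its checkpoint."""
    _check_two_classes(labels)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed & 0x7FFFFFFF, 10]))
    model = ResNet3D(backbone_cfg, rng=rng)
    losses, lrs = _train_loop(model, volumes, labels, train_cfg)
    acc = _train_accuracy(model, volumes, labels)
    ckpt = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "stage1.npz"
        save_checkpoint(model, ckpt, {"backbone": backbone_config_dict(backbone_cfg)})
    return StageResult(ckpt, losses, lrs, acc, train_cfg.seed,
                       config_hash(backbone_cfg, train_cfg), model=model)


def train_stage2(
    volumes: list[Volume],
    labels: list[int],
    stage1: StageResult | Path | str,
    lam_cfg: LamConfig = LamConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    backbone_cfg: BackboneConfig | None = None,
    out_dir=None,
    forced_masks=None,
) -> StageResult:
    """Generate masks from the stage-1 model and train the attention network.

    ``forced_masks`` substitutes precomputed masks (e.g. all-ones) for the
    Grad-CAM ones; otherwise masks come from the stage-1 model under the
    true-label policy and stay fixed for the whole stage.
    """
    _check_two_classes(labels)
    if isinstance(stage1, StageResult) and stage1.model is not None:
        base = stage1.model
        backbone_cfg = backbone_cfg or base.cfg
    else:
        path = stage1.checkpoint if isinstance(stage1, StageResult) else Path(stage1)
        arrays, meta = load_checkpoint(path)
        backbone_cfg = backbone_cfg or backbone_config_from_dict(meta["backbone"])
        base = ResNet3D(backbone_cfg)
        base.load_state_arrays(arrays)
    masks = forced_masks
    if masks is None:
        cache_dir = Path(out_dir) / "masks" if out_dir is not None else None
        masks = cam_mod.batch_generate_masks(
            base, volumes, label_policy="true_label",
            threshold=train_cfg.mask_threshold, layer_name=train_cfg.mask_layer,
            cache_dir=cache_dir,
        )
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed & 0x7FFFFFFF, 20]))
    net = LamNetwork(backbone_cfg, lam_cfg, rng=rng)
    if train_cfg.warm_start:
        net.backbone.load_state_arrays(base.state_arrays())
    losses, lrs = _train_loop(net, volumes, labels, train_cfg, masks=masks)
    acc = _train_accuracy(net, volumes, labels, masks=masks)
    ckpt = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "stage2.npz"
        save_checkpoint(net, ckpt, {
            "backbone": backbone_config_dict(backbone_cfg),
            "lam": asdict(lam_cfg),
        })
    return StageResult(ckpt, losses, lrs, acc, train_cfg.seed,
                       config_hash(backbone_cfg, lam_cfg, train_cfg), model=net)
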