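"""Grad-CAM for the 3D backbone and binarization into lesion masks.

The class-discriminative localization map L^c is the ReLU of the
alpha-weighted sum of the tap layer's activations A^k, where each channel
weight alpha_k^c is the gradient of the class score y^c w.r.t. A^k,
global-average-pooled over all spatial dimensions (Z = their product; the
2D formulation extends to the three spatial axes of a 3D network).  The
map is min-max normalized to [0, 255], upsampled trilinearly to volume
resolution and thresholded at T (default 50): values >= T become 1.  A
constant map carries no localization signal, so it degrades to an
all-ones mask and the attention module falls back to plain self-attention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .backbone import ResNet3D, volume_to_input
from .preprocess import Volume

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 50.0
DEFAULT_LAYER = "stage4"


@dataclass
class CamMap:
    """Nonnegative localization map at tap resolution, (D, H, W) order."""

    values: np.ndarray
    class_index: int
    layer_name: str
    alpha: np.ndarray  # per-channel weights alpha_k^c
    Z: int  # product of the tap layer's spatial extents


@dataclass
class LesionMask:
    """Binary {0,1} mask at volume resolution, (H, W, D) order like Volume."""

    values: np.ndarray
    threshold: float
    source: str  # "true_label" | "predicted"


def gradcam(
    model: ResNet3D,
    volume: Volume | np.ndarray,
    class_index: int,
    layer_name: str = DEFAULT_LAYER,
) -> CamMap:
    """Localization map for ``class_index`` at the named tap layer."""
    if layer_name not in model.cfg.stage_taps:
        raise ValueError(f"{layer_name!r} is not a configured tap {model.cfg.stage_taps}")
    x = volume_to_input(volume)
    scores = model.forward(x, train=False)
    if not 0 <= class_index < scores.shape[1]:
        raise ValueError(f"class_index {class_index} out of range [0, {scores.shape[1]})")
    dlogits = np.zeros_like(scores)
    dlogits[0, class_index] = 1.0
    model.backward(dlogits, capture={layer_name})
    acts = model.features()[layer_name][0]  # (C, D, H, W)
    grads = model.tap_grads[layer_name][0]
    z = int(np.prod(acts.shape[1:]))
    alpha = grads.sum(axis=(1, 2, 3)) / z
    cam = np.tensordot(alpha, acts, axes=1)
    cam = np.maximum(cam, 0.0)
    return CamMap(values=cam, class_index=class_index, layer_name=layer_name, alpha=alpha, Z=z)


def cam_to_mask(
    cam: CamMap | np.ndarray,
    volume_shape: tuple[int, int, int],
    threshold: float = DEFAULT_THRESHOLD,
    source: str = "true_label",
) -> LesionMask:
    """Normalize to [0, 255], upsample to volume resolution, threshold at T.

    ``volume_shape`` is the (H, W, D) shape of the preprocessed volume.
    """
    vals = cam.values if isinstance(cam, CamMap) else np.asarray(cam, dtype=np.float64)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    lo, hi = float(vals.min()), float(vals.max())
    h, w, d = volume_shape
    if hi == lo:
        log.warning("constant localization map: falling back to an all-ones mask")
        mask = np.ones((h, w, d), dtype=np.uint8)
        return LesionMask(values=mask, threshold=threshold, source=source)
    norm = (vals - lo) / (hi - lo) * 255.0
    if norm.shape == (d, h, w):
        up = norm
    else:
        up = resize(norm, (d, h, w), order=1, preserve_range=True, anti_aliasing=False)
    mask = (up >= threshold).astype(np.uint8)
    return LesionMask(values=np.moveaxis(mask, 0, -1), threshold=threshold, source=source)


def batch_generate_masks(
    model: ResNet3D,
    volumes: list[Volume],
    label_policy: str = "true_label",
    threshold: float = DEFAULT_THRESHOLD,
    layer_name: str = DEFAULT_LAYER,
    cache_dir=None,
) -> dict[tuple[str, str], LesionMask]:
    """One mask per volume, keyed by (patient_id, eye_id).

    With ``cache_dir`` set, masks are cached to disk as one compressed
    array per eye plus a JSON sidecar keyed on the model checksum,
    threshold, policy and tap layer; matching entries are reused.
    """
    if label_policy not in ("true_label", "predicted"):
        raise ValueError(f"unknown label_policy {label_policy!r}")
    checksum = model.checksum()
    cache_dir = Path(cache_dir) if cache_dir is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
    out: dict[tuple[str, str], LesionMask] = {}
    for v in volumes:
        key = (v.patient_id, v.eye_id)
        meta = {
            "model_checksum": checksum,
            "threshold": float(threshold),
            "policy": label_policy,
            "layer": layer_name,
        }
        if cache_dir is not None:
            stem = cache_dir / f"{v.patient_id}_{v.eye_id}"
            side = stem.with_suffix(".json")
            npz = stem.with_suffix(".npz")
            if side.exists() and npz.exists():
                try:
                    if json.loads(side.read_text()) == meta:
                        with np.load(npz) as z:
                            out[key] = LesionMask(z["mask"], threshold, label_policy)
                        continue
                except (json.JSONDecodeError, KeyError):
                    log.warning("corrupt mask cache entry %s: regenerating", stem)
        if label_policy == "true_label":
            if v.label is None:
                raise ValueError(f"volume {key} has no label under the true_label policy")
            c = int(v.label)
        else:
            scores = model.forward(volume_to_input(v), train=False)
            c = int(np.argmax(scores[0]))
        cmap = gradcam(model, v, c, layer_name)
        mask = cam_to_mask(cmap, v.data.shape, threshold, source=label_policy)
        out[key] = mask
        if cache_dir is not None:
            np.savez_compressed(npz, mask=mask.values)
            side.write_text(json.dumps(meta, sort_keys=True))
    return out
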