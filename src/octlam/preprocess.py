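"""B-scan preprocessing: macular slice selection to 100x100x70 volumes.

The chain, applied per eye: select slices [130, 270) of the 400-slice
stack (140 slices), subsample at stride 2 (70 slices), crop the middle
140 columns of each 400x640 B-scan, binarize (Otsu by default), dilate
morphologically to connect the retinal foreground, keep the largest
connected component's filled region, zero the background, resize each
masked grayscale slice to 100x100 bilinearly, rescale to [0, 1] and stack
along depth.  There is no randomness anywhere in this module.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .phantom import BScanStack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    slice_lo: int = 130
    slice_hi: int = 270
    sample_stride: int = 2
    crop_width: int = 140
    dilation_kernel: int = 5
    dilation_iters: int = 2
    out_xy: int = 100
    out_depth: int = 70
    binarize_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 25.0

    def __post_init__(self):
        if self.binarize_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown binarize_method {self.binarize_method!r}")
        if self.out_xy < 1 or self.out_depth < 1:
            raise ValueError("out_xy and out_depth must be >= 1")


@dataclass
class Volume:
    """A preprocessed (out_xy, out_xy, out_depth) intensity volume in [0, 1]."""

    data: np.ndarray
    patient_id: str
    eye_id: str
    label: int


def select_slices(stack: BScanStack, cfg: PreprocessConfig = PreprocessConfig()) -> list[np.ndarray]:
    """Slices [slice_lo, slice_hi) subsampled by sample_stride."""
    if stack.n_slices < cfg.slice_hi:
        raise ValueError(
            f"stack has {stack.n_slices} slices; need at least {cfg.slice_hi}"
        )
    return stack.slices[cfg.slice_lo : cfg.slice_hi : cfg.sample_stride]


def center_crop(sl: np.ndarray, crop_width: int) -> np.ndarray:
    """Keep the middle ``crop_width`` columns; height unchanged."""
    w = sl.shape[1]
    if crop_width > w:
        raise ValueError(f"crop_width {crop_width} exceeds slice width {w}")
    left = (w - crop_width) // 2
    return sl[:, left : left + crop_width]


def binarize_slice(sl: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """{0,1} mask; a pixel is 1 iff its intensity >= the threshold."""
    sl = np.asarray(sl)
    if sl.size == 0:
        raise ValueError("empty slice")
    if cfg.binarize_method == "fixed" or sl.min() == sl.max():
        if cfg.binarize_method == "otsu" and sl.min() == sl.max():
            log.warning("constant slice: Otsu undefined, falling back to fixed threshold")
        t = cfg.fixed_threshold
    else:
        t = threshold_otsu(sl)
    return (sl >= t).astype(np.uint8)


def _ellipse_footprint(kernel: int) -> np.ndarray:
    r = max((kernel - 1) // 2, 0)
    if r == 0:
        return np.ones((1, 1), dtype=bool)
    # disk(r) is the (2r+1)-pixel elliptical element (x/r)^2 + (y/r)^2 <= 1
    return morphology.disk(r).astype(bool)


def dilate(mask: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Repeated dilation with an elliptical footprint; extensive (1s kept)."""
    fp = _ellipse_footprint(cfg.dilation_kernel)
    out = ndi.binary_dilation(mask.astype(bool), structure=fp, iterations=cfg.dilation_iters)
    return out.astype(np.uint8)


def extract_foreground(sl: np.ndarray, dilated_mask: np.ndarray) -> np.ndarray:
    """Zero everything outside the largest connected component's filled region."""
    if sl.shape != dilated_mask.shape:
        raise ValueError(f"shape mismatch {sl.shape} vs {dilated_mask.shape}")
    labeled, n = measure.label(dilated_mask > 0, connectivity=2, return_num=True)
    if n == 0:
        log.warning("empty mask: returning slice unchanged")
        return np.asarray(sl).copy()
    areas = np.bincount(labeled.ravel())[1:]
    keep = labeled == (int(np.argmax(areas)) + 1)
    region = ndi.binary_fill_holes(keep)
    return np.asarray(sl) * region


def preprocess_slice(sl: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """crop -> binarize -> dilate -> extract -> resize -> [0,1] for one B-scan."""
    cropped = center_crop(sl, cfg.crop_width)
    mask = binarize_slice(cropped, cfg)
    dil = dilate(mask, cfg)
    fg = extract_foreground(cropped, dil)
    small = resize(
        fg.astype(np.float64), (cfg.out_xy, cfg.out_xy), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return np.clip(small / 255.0, 0.0, 1.0)


def assemble_volume(stack: BScanStack, cfg: PreprocessConfig = PreprocessConfig()) -> Volume:
    """Run the full chain over a stack and stack the slices along depth."""
    selected = select_slices(stack, cfg)
    data = np.empty((cfg.out_xy, cfg.out_xy, len(selected)), dtype=np.float64)
    for i, sl in enumerate(selected):
        try:
            data[:, :, i] = preprocess_slice(sl, cfg)
        except Exception as exc:
            raise type(exc)(f"slice {i}: {exc}") from exc
    return Volume(data=data, patient_id=stack.patient_id, eye_id=stack.eye_id, label=stack.label)


def save_volumes(volumes: list[Volume], out_dir) -> Path:
    """One compressed array file per eye plus a manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "volumes.tsv"
    with open(manifest, "w", newline="") as f:
        wtr = csv.writer(f, delimiter="\t")
        wtr.writerow(["patient_id", "eye_id", "label", "path"])
        for v in volumes:
            p = out_dir / f"{v.patient_id}_{v.eye_id}.npz"
            np.savez_compressed(p, data=v.data)
            wtr.writerow([v.patient_id, v.eye_id, v.label, p.name])
    return manifest


def load_volumes(manifest) -> list[Volume]:
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest {manifest}")
    out = []
    with open(manifest) as f:
        for row in csv.DictReader(f, delimiter="\t"):
            with np.load(manifest.parent / row["path"]) as z:
                data = z["data"]
            out.append(Volume(data=data, patient_id=row["patient_id"],
                              eye_id=row["eye_id"], label=int(row["label"])))
    return out


def config_dict(cfg: PreprocessConfig) -> dict:
    return asdict(cfg)
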