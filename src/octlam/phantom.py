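"""Synthetic OCT B-scan phantoms.

Real acquisitions image the macular region as a stack of 2D cross-sections
(B-scans): smooth bright retinal bands on a dark background, 400 slices of
400x640 pixels per eye.  The phantom emulates exactly that geometry —
``n_layers`` polynomial bands whose curvature varies smoothly per patient
and per slice, Gaussian intensity noise, and an optional hyperreflective
spherical lesion.  Diabetic-nephropathy (DN) eyes receive a bright lesion
near the central slices and central columns, so that the macular crop of
the preprocessing chain retains it; diabetic-retinopathy (DR) eyes receive
only a small peripheral blob that the crop removes.  The label is therefore
carried by image content that survives preprocessing, which is what the
downstream classification experiments rely on.

Determinism: an identical ``PhantomSpec`` (including ``seed``) yields
bit-identical output; per-slice noise streams are derived from
``(seed, slice_index)`` so single slices can be generated independently.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

DR, DN = 0, 1
LABEL_NAMES = {DR: "DR", DN: "DN"}

# lesion placement window as fractions of the stack geometry; with the
# default 400-slice / 400-px geometry this is slices [130, 270) and the
# central 140 columns, i.e. the region the macular crop retains
_SLICE_LO_FRAC, _SLICE_HI_FRAC = 130 / 400, 270 / 400
_CENTER_WIDTH_FRAC = 140 / 400


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of one synthetic eye."""

    width: int = 400
    height: int = 640
    n_slices: int = 400
    n_layers: int = 5
    lesion_present: bool = False
    lesion_center: tuple[int, int, int] | None = None  # (slice, x, y)
    lesion_radius: float = 12.0
    noise_sigma: float = 8.0
    background: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height, self.n_slices) < 1:
            raise ValueError("width, height and n_slices must be >= 1")
        if self.lesion_radius < 0 or self.noise_sigma < 0:
            raise ValueError("lesion_radius and noise_sigma must be >= 0")

    def resolved_lesion_center(self) -> tuple[int, int, int]:
        if self.lesion_center is not None:
            return self.lesion_center
        return (self.n_slices // 2, self.width // 2, self.height // 2)


@dataclass
class BScanStack:
    """One eye's ordered raw B-scans plus identifiers and class label."""

    slices: list[np.ndarray]
    patient_id: str
    eye_id: str
    label: int

    def __post_init__(self):
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes: {shapes}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def _band_params(spec: PhantomSpec):
    """Per-patient band geometry, drawn from the structure stream of ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 1]))
    n = spec.n_layers
    centers = np.linspace(0.32, 0.68, n) * spec.height
    centers += rng.uniform(-0.01, 0.01, n) * spec.height
    # low-order polynomial curvature in x, slowly modulated along the stack
    coefs = rng.uniform(-1.0, 1.0, size=(n, 3)) * spec.height * np.array([0.01, 0.02, 0.03])
    zcoefs = rng.uniform(-1.0, 1.0, size=n) * spec.height * 0.015
    thickness = np.maximum(2.0, rng.uniform(0.008, 0.016, n) * spec.height)
    intensity = rng.uniform(150.0, 235.0, n)
    return centers, coefs, zcoefs, thickness, intensity


def _lesion_disc(spec: PhantomSpec, slice_index: int):
    """(x, y, radius) of the lesion sphere's intersection with a slice, or None."""
    if not spec.lesion_present:
        return None
    cz, cx, cy = spec.resolved_lesion_center()
    dz = slice_index - cz
    r2 = spec.lesion_radius**2 - dz**2
    if r2 <= 0:
        return None
    return cx, cy, float(np.sqrt(r2))


def generate_bscan(spec: PhantomSpec, slice_index: int) -> np.ndarray:
    """One (height, width) uint8 B-scan; deterministic in (spec, slice_index)."""
    if not 0 <= slice_index < spec.n_slices:
        raise IndexError(f"slice_index {slice_index} out of range [0, {spec.n_slices})")
    centers, coefs, zcoefs, thickness, intensity = _band_params(spec)
    h, w = spec.height, spec.width
    img = np.full((h, w), spec.background, dtype=np.float64)
    u = np.linspace(-0.5, 0.5, w)
    zfrac = slice_index / max(spec.n_slices - 1, 1) - 0.5
    rows = np.arange(h, dtype=np.float64)[:, None]
    for i in range(spec.n_layers):
        y = centers[i] + coefs[i, 0] * u + coefs[i, 1] * u**2 + coefs[i, 2] * u**3
        y = y + zcoefs[i] * zfrac
        band = np.abs(rows - y[None, :]) <= thickness[i]
        img[band] = np.maximum(img[band], intensity[i])
    disc = _lesion_disc(spec, slice_index)
    if disc is not None:
        cx, cy, r = disc
        xs = np.arange(w, dtype=np.float64)[None, :]
        inside = (xs - cx) ** 2 + (rows - cy) ** 2 <= r**2
        img[inside] = 245.0
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 2, int(slice_index)])
        )
        img += noise_rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_stack(
    spec: PhantomSpec, patient_id: str = "P000", eye_id: str = "OD", label: int = DR
) -> BScanStack:
    slices = [generate_bscan(spec, i) for i in range(spec.n_slices)]
    return BScanStack(slices=slices, patient_id=patient_id, eye_id=eye_id, label=label)


def generate_dataset(
    n_patients: int,
    dn_fraction: float,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[BScanStack]:
    """One labeled stack per patient, DN prevalence ``dn_fraction``.

    DN eyes get a lesion inside the central slice/column window so the
    macular crop keeps it; DR eyes get a small peripheral blob outside the
    cropped region (so raw "has any blob" is not the class signal).
    """
    if not 0 <= dn_fraction <= 1:
        raise ValueError(f"dn_fraction must be in [0, 1], got {dn_fraction}")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 3]))
    n_dn = int(round(n_patients * dn_fraction))
    labels = np.array([DN] * n_dn + [DR] * (n_patients - n_dn))
    rng.shuffle(labels)

    ns, w, h = base_spec.n_slices, base_spec.width, base_spec.height
    zlo, zhi = int(ns * _SLICE_LO_FRAC), int(ns * _SLICE_HI_FRAC)
    half_win = int(w * _CENTER_WIDTH_FRAC / 2)
    stacks = []
    for i, label in enumerate(labels):
        pseed = int(rng.integers(0, 2**31 - 1))
        y = int(h * rng.uniform(0.42, 0.58))
        if label == DN:
            cz = int(rng.integers(zlo + int(base_spec.lesion_radius), zhi - int(base_spec.lesion_radius)))
            cx = int(w // 2 + rng.integers(-half_win // 2, half_win // 2 + 1))
            radius = float(base_spec.lesion_radius * rng.uniform(1.0, 1.4))
        else:
            # peripheral blob, fully outside the central crop window
            cz = int(rng.integers(0, max(zlo - 1, 1)))
            margin = int(base_spec.lesion_radius) + 2
            cx = int(rng.choice([rng.integers(margin, max(w // 2 - half_win - margin, margin + 1)),
                                 rng.integers(min(w // 2 + half_win + margin, w - margin - 1), w - margin)]))
            radius = float(base_spec.lesion_radius * rng.uniform(0.4, 0.7))
        spec = dataclasses.replace(
            base_spec,
            seed=pseed,
            lesion_present=True,
            lesion_center=(cz, cx, y),
            lesion_radius=radius,
        )
        stacks.append(generate_stack(spec, patient_id=f"P{i:03d}", eye_id="OD", label=int(label)))
    return stacks


def write_dataset(stacks: list[BScanStack], out_dir) -> Path:
    """One directory per eye of zero-padded PNGs plus a labels.tsv manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in stacks:
        eye_dir = out_dir / f"{st.patient_id}_{st.eye_id}"
        eye_dir.mkdir(exist_ok=True)
        for i, sl in enumerate(st.slices):
            iio.imwrite(eye_dir / f"slice_{i:04d}.png", sl)
        rows.append((st.patient_id, st.eye_id, st.label))
    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w", newline="") as f:
        wtr = csv.writer(f, delimiter="\t")
        wtr.writerow(["patient_id", "eye_id", "label"])
        wtr.writerows(rows)
    return labels_path


def read_dataset(data_dir) -> list[BScanStack]:
    """Read a directory tree written by :func:`write_dataset` (PNG or TIFF)."""
    data_dir = Path(data_dir)
    labels_path = data_dir / "labels.tsv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing manifest {labels_path}")
    stacks = []
    with open(labels_path) as f:
        rdr = csv.DictReader(f, delimiter="\t")
        for row in rdr:
            eye_dir = data_dir / f"{row['patient_id']}_{row['eye_id']}"
            files = sorted(eye_dir.glob("slice_*.png")) + sorted(eye_dir.glob("slice_*.tif*"))
            if not files:
                raise FileNotFoundError(f"no slices under {eye_dir}")
            slices = [np.asarray(iio.imread(p)) for p in files]
            stacks.append(
                BScanStack(
                    slices=slices,
                    patient_id=row["patient_id"],
                    eye_id=row["eye_id"],
                    label=int(row["label"]),
                )
            )
    return stacks
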