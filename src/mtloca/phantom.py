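"""Synthetic breast-ultrasound-like speckle phantoms with ground truth.

Generates grayscale images containing no lesion (normal), a smooth
hypoechoic ellipse (benign), or an irregular spiculated dark region
(malignant), each paired with a pixel-exact binary mask, so the whole
pipeline can be exercised without any external dataset.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

CLASSES = ("normal", "benign", "malignant")

__all__ = [
    "CLASSES", "PhantomSpec", "LabeledSample", "SpeckleParams",
    "BenignShape", "MalignantShape", "generate_sample", "generate_dataset",
    "class_counts", "load_dataset", "load_sample",
]


@dataclasses.dataclass(frozen=True)
class BenignShape:
    """Axis-aligned-ish smooth ellipse, in pixels."""
    axis_min: float = 10.0
    axis_max: float = 26.0
    contrast: float = 0.40  # fractional darkening inside the lesion


@dataclasses.dataclass(frozen=True)
class MalignantShape:
    """Spiculated star-like region: r(theta) = r0 * (1 + a * sum sin(k theta + phi))."""
    radius_min: float = 10.0
    radius_max: float = 22.0
    amplitude: float = 0.35   # total relative boundary perturbation
    n_spikes: int = 4         # number of sinusoidal harmonics
    freq_min: int = 5
    freq_max: int = 9
    contrast: float = 0.65  # deeper hypoechogenicity than benign lesions


@dataclasses.dataclass(frozen=True)
class SpeckleParams:
    """Multiplicative Rayleigh speckle, normalized to unit mean.

    ``strength`` scales the deviation from 1:  N = 1 + strength * (R/E[R] - 1)
    with R ~ Rayleigh.  ``smooth_sigma`` > 0 blurs the noise field to mimic
    correlated speckle (off by default so the variance is analytic).
    """
    strength: float = 0.5
    smooth_sigma: float = 0.0

    @property
    def variance(self) -> float:
        """Per-pixel variance of the unsmoothed multiplicative field."""
        return self.strength ** 2 * (4.0 - np.pi) / np.pi


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 128
    class_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"normal": 1 / 3, "benign": 1 / 3, "malignant": 1 / 3})
    benign_shape: BenignShape = dataclasses.field(default_factory=BenignShape)
    malignant_shape: MalignantShape = dataclasses.field(default_factory=MalignantShape)
    speckle: SpeckleParams = dataclasses.field(default_factory=SpeckleParams)
    background_intensity: float = 0.55
    margin: int = 4
    seed: int = 0

    def validate(self):
        if not 0.0 < self.background_intensity <= 1.0:
            raise ValueError("background_intensity must lie in (0, 1]")
        if not 0.0 <= self.benign_shape.contrast <= 1.0:
            raise ValueError("benign contrast must lie in [0, 1]")
        if not 0.0 <= self.malignant_shape.contrast <= 1.0:
            raise ValueError("malignant contrast must lie in [0, 1]")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        for k in self.class_mix:
            if k not in CLASSES:
                raise ValueError(f"unknown class {k!r}")


@dataclasses.dataclass
class LabeledSample:
    image: np.ndarray   # (H, W) float in [0, 1]
    mask: np.ndarray    # (H, W) uint8 in {0, 1}
    label: str          # normal | benign | malignant
    id: str

    def validate(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image/mask shape mismatch")
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if not set(np.unique(self.mask)) <= {0, 1}:
            raise ValueError("mask must be binary")
        if (self.label == "normal") != (self.mask.sum() == 0):
            raise ValueError("label 'normal' must coincide with an empty mask")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")


class LesionSizingError(ValueError):
    """Requested lesion cannot fit inside the image with the required margin."""


def _lesion_center(size: int, max_extent: float, margin: int,
                   rng: np.random.Generator) -> tuple[float, float]:
    lo = max_extent + margin
    hi = size - 1 - max_extent - margin
    if hi <= lo:
        raise LesionSizingError(
            f"lesion extent {max_extent:.1f}px + margin {margin}px does not fit "
            f"in a {size}px image")
    return rng.uniform(lo, hi), rng.uniform(lo, hi)


def _benign_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    sh = spec.benign_shape
    a = rng.uniform(sh.axis_min, sh.axis_max)
    b = rng.uniform(sh.axis_min, sh.axis_max)
    theta = rng.uniform(0, np.pi)
    cy, cx = _lesion_center(spec.image_size, max(a, b), spec.margin, rng)
    yy, xx = np.mgrid[0:spec.image_size, 0:spec.image_size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _malignant_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    sh = spec.malignant_shape
    r0 = rng.uniform(sh.radius_min, sh.radius_max)
    freqs = rng.integers(sh.freq_min, sh.freq_max + 1, size=sh.n_spikes)
    phases = rng.uniform(0, 2 * np.pi, size=sh.n_spikes)
    # per-harmonic amplitudes sum to the configured total perturbation
    amps = np.full(sh.n_spikes, sh.amplitude / sh.n_spikes)
    max_extent = r0 * (1.0 + sh.amplitude)
    cy, cx = _lesion_center(spec.image_size, max_extent, spec.margin, rng)
    yy, xx = np.mgrid[0:spec.image_size, 0:spec.image_size]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)
    boundary = r0 * (1.0 + np.sum(
        [a * np.sin(k * ang + p) for a, k, p in zip(amps, freqs, phases)], axis=0))
    return (rr <= boundary).astype(np.uint8)


def render_clean(spec: PhantomSpec, label: str,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free phantom: hypoechoic lesion on a uniform background.

    Returns (clean_image, mask). Exposed separately so the hypoechoic
    contract can be tested before speckle is applied.
    """
    spec.validate()
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    size = spec.image_size
    bg = spec.background_intensity
    if label == "normal":
        return np.full((size, size), bg, dtype=np.float64), np.zeros((size, size), np.uint8)
    if label == "benign":
        mask = _benign_mask(spec, rng)
        contrast = spec.benign_shape.contrast
        edge_sigma = 1.5  # smooth margin, as expected of benign morphology
    else:
        mask = _malignant_mask(spec, rng)
        contrast = spec.malignant_shape.contrast
        edge_sigma = 0.6
    lesion = ndimage.gaussian_filter(mask.astype(np.float64), edge_sigma)
    clean = bg * (1.0 - contrast * lesion)
    return clean, mask


def _speckle_field(shape, params: SpeckleParams, rng: np.random.Generator) -> np.ndarray:
    r = rng.rayleigh(scale=1.0, size=shape)
    n = r / np.sqrt(np.pi / 2.0)          # unit mean
    field = 1.0 + params.strength * (n - 1.0)
    if params.smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, params.smooth_sigma)
    return field


def generate_sample(spec: PhantomSpec, label: str,
                    rng: np.random.Generator, sample_id: str = "s0") -> LabeledSample:
    """One phantom image + mask + label for the requested class."""
    clean, mask = render_clean(spec, label, rng)
    image = np.clip(clean * _speckle_field(clean.shape, spec.speckle, rng), 0.0, 1.0)
    sample = LabeledSample(image=image, mask=mask, label=label, id=sample_id)
    sample.validate()
    return sample


def class_counts(class_mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` samples to the class mix."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = [c for c in CLASSES if class_mix.get(c, 0.0) > 0]
    exact = {c: class_mix[c] * n for c in labels}
    counts = {c: int(np.floor(exact[c])) for c in labels}
    short = n - sum(counts.values())
    for c in sorted(labels, key=lambda c: exact[c] - np.floor(exact[c]), reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_dataset(spec: PhantomSpec, n: int,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[LabeledSample], pd.DataFrame]:
    """Generate ``n`` phantoms following ``spec.class_mix``.

    If ``out_dir`` is given, writes ``images/<id>.png``, ``masks/<id>.png``
    (8-bit, masks as {0,255}) and ``manifest.csv``. Deterministic in
    (spec, n): identical arguments give byte-identical outputs.
    """
    spec.validate()
    counts = class_counts(spec.class_mix, n)
    rng = np.random.default_rng(spec.seed)
    samples: list[LabeledSample] = []
    rows = []
    idx = 0
    for label in CLASSES:
        for _ in range(counts.get(label, 0)):
            sid = f"s{idx:04d}_{label}"
            samples.append(generate_sample(spec, label, rng, sample_id=sid))
            idx += 1
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        row = {"id": s.id, "label": s.label,
               "image_path": f"images/{s.id}.png", "mask_path": f"masks/{s.id}.png"}
        rows.append(row)
        if out_dir is not None:
            img8 = np.round(s.image * 255.0).astype(np.uint8)
            Image.fromarray(img8).save(Path(out_dir) / row["image_path"])
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                Path(out_dir) / row["mask_path"])
    manifest = pd.DataFrame(rows, columns=["id", "label", "image_path", "mask_path"])
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return samples, manifest


def load_sample(root: str | Path, row) -> LabeledSample:
    """Load one manifest row back into a LabeledSample."""
    root = Path(root)
    img = np.asarray(Image.open(root / row["image_path"]).convert("L"),
                     dtype=np.float64) / 255.0
    mask = (np.asarray(Image.open(root / row["mask_path"]).convert("L")) > 127
            ).astype(np.uint8)
    s = LabeledSample(image=img, mask=mask, label=row["label"], id=row["id"])
    s.validate()
    return s


def load_dataset(root: str | Path) -> tuple[list[LabeledSample], pd.DataFrame]:
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    samples = [load_sample(root, row) for _, row in manifest.iterrows()]
    return samples, manifest
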