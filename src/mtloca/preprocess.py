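"""Input preparation: grayscale conversion, resizing, Gaussian-derivative
boundary features, channel concatenation, and training-time augmentation.

The derivative-of-Gaussian magnitude is concatenated with the intensity
image as a second input channel; it highlights lesion boundaries.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .phantom import CLASSES, LabeledSample

TARGET_SIZE = 128

#: Rec. 709 luma weights for RGB -> grayscale.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

__all__ = [
    "TARGET_SIZE", "DerivativeConfig", "AugmentConfig", "ModelInput",
    "to_grayscale", "gaussian_kernel_2d", "gaussian_derivative_kernels",
    "gradient_magnitude", "build_model_input", "augment", "label_index",
]


def label_index(label: str) -> int:
    return CLASSES.index(label)


@dataclasses.dataclass(frozen=True)
class DerivativeConfig:
    """Gaussian kernel width (pixels) and truncation radius (in sigmas)."""
    sigma: float = 1.5
    kernel_radius: float = 4.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_radius < 2:
            raise ValueError("kernel_radius must be >= 2")

    @property
    def half_width(self) -> int:
        return int(np.ceil(self.kernel_radius * self.sigma))


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    rotation_range: tuple[float, float] = (-45.0, 45.0)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    crop_prob: float = 0.5
    crop_fraction: float = 0.8
    gamma_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self):
        if not 0.0 <= self.crop_prob <= 1.0:
            raise ValueError("crop_prob must lie in [0, 1]")
        lo, hi = self.rotation_range
        if abs(lo + hi) > 1e-9:
            raise ValueError("rotation_range must be symmetric about zero")


@dataclasses.dataclass
class ModelInput:
    """Network-ready sample: stacked channels, class index, binary target."""
    channels: np.ndarray  # (C, 128, 128) float32; 0 = intensity, 1 = edge magnitude
    mask: np.ndarray      # (128, 128) uint8 in {0, 1}
    label: int            # index into CLASSES
    id: str = ""

    def validate(self):
        if self.channels.shape[1:] != (TARGET_SIZE, TARGET_SIZE):
            raise ValueError("channels must be C x 128 x 128")
        if self.mask.shape != (TARGET_SIZE, TARGET_SIZE):
            raise ValueError("mask must be 128 x 128")
        if not set(np.unique(self.mask)) <= {0, 1}:
            raise ValueError("mask must stay binary")
        if self.label not in range(len(CLASSES)):
            raise ValueError("label index out of range")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec. 709 luminance of an (H, W, 3) image in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) color image, got {image.shape}")
    return image @ _LUMA


def _grid(cfg: DerivativeConfig) -> tuple[np.ndarray, np.ndarray]:
    r = cfg.half_width
    coords = np.arange(-r, r + 1, dtype=np.float64)
    return np.meshgrid(coords, coords, indexing="xy")  # x varies along columns


def gaussian_kernel_2d(cfg: DerivativeConfig) -> np.ndarray:
    """Sampled 2-D Gaussian: G(x, y) = exp(-(x^2+y^2)/(2 sigma^2)) / (2 pi sigma^2)."""
    x, y = _grid(cfg)
    s2 = cfg.sigma ** 2
    return np.exp(-(x ** 2 + y ** 2) / (2 * s2)) / (2 * np.pi * s2)


def gaussian_derivative_kernels(cfg: DerivativeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sampled partial derivatives of the Gaussian w.r.t. x and y.

    dG/dx = -x / (2 pi sigma^4) * exp(-(x^2+y^2) / (2 sigma^2)); dG/dy is its
    transpose. Both kernels sum to zero by antisymmetry.
    """
    x, y = _grid(cfg)
    s2 = cfg.sigma ** 2
    env = np.exp(-(x ** 2 + y ** 2) / (2 * s2)) / (2 * np.pi * s2 ** 2)
    kdx = -x * env
    kdy = -y * env
    return kdx, kdy


def gradient_magnitude(image: np.ndarray, cfg: DerivativeConfig) -> np.ndarray:
    """sqrt(gx^2 + gy^2) of the Gaussian-smoothed image (reflect borders)."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    kdx, kdy = gaussian_derivative_kernels(cfg)
    if min(image.shape) < kdx.shape[0]:
        raise ValueError(f"image {image.shape} smaller than kernel {kdx.shape}")
    gx = ndimage.convolve(image, kdx, mode="reflect")
    gy = ndimage.convolve(image, kdy, mode="reflect")
    return np.hypot(gx, gy)


def _resize_intensity(image: np.ndarray) -> np.ndarray:
    if image.shape == (TARGET_SIZE, TARGET_SIZE):
        return image.astype(np.float64)
    return transform.resize(image, (TARGET_SIZE, TARGET_SIZE), order=1,
                            anti_aliasing=True, preserve_range=True)


def _resize_mask(mask: np.ndarray) -> np.ndarray:
    if mask.shape == (TARGET_SIZE, TARGET_SIZE):
        return mask.astype(np.uint8)
    out = transform.resize(mask.astype(np.float64), (TARGET_SIZE, TARGET_SIZE),
                           order=0, anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def build_model_input(sample: LabeledSample,
                      cfg: DerivativeConfig | None = None) -> ModelInput:
    """Resize to 128x128, append the edge-magnitude channel, binarize the mask.

    The magnitude channel is rescaled by its per-image maximum so both
    channels share the [0, 1] dynamic range.
    """
    cfg = cfg or DerivativeConfig()
    sample.validate()
    intensity = _resize_intensity(np.asarray(sample.image, dtype=np.float64))
    mag = gradient_magnitude(intensity, cfg)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    channels = np.stack([intensity, mag]).astype(np.float32)
    mi = ModelInput(channels=channels, mask=_resize_mask(sample.mask),
                    label=label_index(sample.label), id=sample.id)
    mi.validate()
    return mi


def _rotate_stack(channels: np.ndarray, mask: np.ndarray, angle: float):
    rot = np.stack([
        transform.rotate(c, angle, order=1, mode="edge", preserve_range=True)
        for c in channels])
    rmask = transform.rotate(mask.astype(np.float64), angle, order=0,
                             mode="constant", cval=0.0, preserve_range=True)
    return rot, (rmask > 0.5).astype(np.uint8)


def _center_crop_stack(channels: np.ndarray, mask: np.ndarray, fraction: float):
    h, w = mask.shape
    ch, cw = int(round(h * fraction)), int(round(w * fraction))
    top, left = (h - ch) // 2, (w - cw) // 2
    cropped = channels[:, top:top + ch, left:left + cw]
    cmask = mask[top:top + ch, left:left + cw]
    up = np.stack([_resize_intensity(c) for c in cropped])
    return up, _resize_mask(cmask)


def augment(mi: ModelInput, cfg: AugmentConfig,
            rng: np.random.Generator) -> ModelInput:
    """Seeded geometric + intensity augmentation.

    The same geometric transform hits every channel and the mask; the
    contrast (gamma) transform touches the intensity channel only.
    """
    channels = mi.channels.astype(np.float64)
    mask = mi.mask.copy()

    lo, hi = cfg.rotation_range
    angle = rng.uniform(lo, hi)
    if angle != 0.0:
        channels, mask = _rotate_stack(channels, mask, angle)
    if cfg.flip_horizontal and rng.random() < 0.5:
        channels = channels[:, :, ::-1]
        mask = mask[:, ::-1]
    if cfg.flip_vertical and rng.random() < 0.5:
        channels = channels[:, ::-1, :]
        mask = mask[::-1, :]
    if cfg.crop_prob > 0 and rng.random() < cfg.crop_prob:
        channels, mask = _center_crop_stack(channels, mask, cfg.crop_fraction)

    glo, ghi = cfg.gamma_range
    if (glo, ghi) != (1.0, 1.0):
        gamma = rng.uniform(glo, ghi)
        channels = channels.copy()
        channels[0] = np.clip(channels[0], 0.0, 1.0) ** gamma

    out = ModelInput(channels=np.clip(channels, 0.0, 1.0).astype(np.float32),
                     mask=np.ascontiguousarray(mask), label=mi.label, id=mi.id)
    out.validate()
    return out


def equalize_intensity(mi: ModelInput, clip_limit: float = 0.01) -> ModelInput:
    """Optional dataset-level CLAHE on the intensity channel."""
    channels = mi.channels.copy()
    channels[0] = exposure.equalize_adapthist(
        np.clip(channels[0], 0, 1), clip_limit=clip_limit).astype(np.float32)
    return ModelInput(channels=channels, mask=mi.mask, label=mi.label, id=mi.id)
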