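"""Object contextual attention: soft object regions, region representations,
pixel-region relations, contextual features, and the augmented segmentation.

The module partitions pixels into K soft object regions d_k (supervised as
coarse segmentation masks), aggregates per-region feature vectors
f_k = sum_i d_k^i x_i, relates every pixel back to the regions through a
softmax over learned compatibility scores, and redistributes region context
to pixels, which is concatenated with the pixel features for the final
segmentation logits.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .backbone import PixelRepresentations
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "OCAConfig", "SoftObjectRegions", "ObjectRegionRepresentations",
    "PixelRegionRelation", "AugmentedRepresentation", "OCAModule",
    "predict_mask",
]


@dataclasses.dataclass(frozen=True)
class OCAConfig:
    num_regions: int = 2
    key_channels: int = 64
    context_channels: int = 64
    groupnorm_groups: int = 8
    #: "pixels": d_k softmax-normalized across pixels, so f_k is a convex
    #: combination dominated by peak-logit pixels.
    #: "mass": per-pixel softmax over regions, each region row divided by its
    #: total mass, so f_k is the soft average (prototype) of its pixels.
    region_weight_norm: str = "pixels"
    #: identity mode: no learned transforms; compatibility is a plain dot
    #: product and the context transforms are identities (used by the
    #: brute-force equivalence oracle).
    identity_transforms: bool = False

    def __post_init__(self):
        if self.num_regions < 2:
            raise ValueError("need at least two object regions")
        if self.region_weight_norm not in ("pixels", "mass"):
            raise ValueError("region_weight_norm must be 'pixels' or 'mass'")


@dataclasses.dataclass
class SoftObjectRegions:
    logits: Tensor   # (N, K, H, W) raw coarse-mask logits (Lsoft target)
    weights: Tensor  # (N, K, H*W) aggregation weights for region pooling

    @property
    def num_regions(self) -> int:
        return self.logits.shape[1]


@dataclasses.dataclass
class ObjectRegionRepresentations:
    f: Tensor  # (N, K, C_f)


@dataclasses.dataclass
class PixelRegionRelation:
    w: Tensor  # (N, H*W, K), rows sum to 1


@dataclasses.dataclass
class AugmentedRepresentation:
    features: Tensor    # (N, C_f + C_ctx, H, W) concatenated representation
    seg_logits: Tensor  # (N, K, H, W)


class OCAModule(nn.Module):
    def __init__(self, in_channels: int, cfg: OCAConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_channels = in_channels
        k = cfg.num_regions
        self.soft_conv = nn.Conv2d(in_channels, k, 1, rng)
        if cfg.identity_transforms:
            self.context_channels = in_channels
        else:
            self.pixel_key = nn.Conv2d(in_channels, cfg.key_channels, 1, rng)
            self.region_key = nn.Linear(in_channels, cfg.key_channels, rng)
            self.h_transform = nn.Linear(in_channels, cfg.context_channels, rng)
            # Normalize the K region prototypes across channels (not across
            # space): the redistributed context map is nearly constant over
            # space, so a spatial norm would amplify that tiny variation to
            # unit variance and drown the pixel features in noise, while an
            # unnormalized pathway lets the context magnitude run away.
            self.h_norm = nn.GroupNorm(1, cfg.context_channels)
            self.delta_conv = nn.Conv2d(cfg.context_channels, cfg.context_channels, 1, rng)
            self.context_channels = cfg.context_channels
        self.aug_conv = nn.Conv2d(in_channels + self.context_channels, k, 1, rng)

    # -- the four pipeline stages --------------------------------------
    def soft_regions(self, x: PixelRepresentations) -> SoftObjectRegions:
        """Learned K-way soft assignment; raw logits double as coarse masks."""
        logits = self.soft_conv(x.features)
        n, k, h, w = logits.shape
        flat = F.reshape(logits, (n, k, h * w))
        if self.cfg.region_weight_norm == "pixels":
            weights = F.softmax(flat, axis=2)
        else:  # "mass": soft assignment per pixel, then unit mass per region
            assign = F.softmax(flat, axis=1)
            mass = F.sum(assign, axis=2, keepdims=True)
            weights = F.mul(assign, F.reciprocal(mass))
        return SoftObjectRegions(logits=logits, weights=weights)

    def region_representations(self, x: PixelRepresentations,
                               d: SoftObjectRegions) -> ObjectRegionRepresentations:
        """f_k = sum_i d_k^i x_i."""
        feats = x.features
        n, c, h, w = feats.shape
        if d.weights.shape[0] != n or d.weights.shape[2] != h * w:
            raise ValueError("soft regions do not match pixel representations")
        xt = F.transpose(F.reshape(feats, (n, c, h * w)), (0, 2, 1))  # (N, HW, C)
        f = F.matmul(d.weights, xt)                                   # (N, K, C)
        return ObjectRegionRepresentations(f=f)

    def pixel_region_relation(self, x: PixelRepresentations,
                              f: ObjectRegionRepresentations) -> PixelRegionRelation:
        """w_ik = softmax_k of compatibility(x_i, f_k)."""
        feats = x.features
        n, c, h, w = feats.shape
        if self.cfg.identity_transforms:
            q = F.transpose(F.reshape(feats, (n, c, h * w)), (0, 2, 1))  # (N, HW, C)
            keys = f.f                                                   # (N, K, C)
            scores = F.matmul(q, F.transpose(keys, (0, 2, 1)))           # (N, HW, K)
        else:
            qmap = self.pixel_key(feats)
            q = F.transpose(F.reshape(qmap, (n, -1, h * w)), (0, 2, 1))
            keys = F.relu(self.region_key(f.f))
            scores = F.mul(F.matmul(q, F.transpose(keys, (0, 2, 1))),
                           1.0 / np.sqrt(self.cfg.key_channels))
        if not np.all(np.isfinite(scores.data)):
            raise FloatingPointError("non-finite pixel-region compatibility scores")
        return PixelRegionRelation(w=F.softmax(scores, axis=2))

    def contextual_representation(self, w: PixelRegionRelation,
                                  f: ObjectRegionRepresentations) -> Tensor:
        """y_i = delta(sum_k w_ik * H(f_k)); returns (N, C_ctx, H*W) map."""
        if self.cfg.identity_transforms:
            hf = f.f
            ctx = F.matmul(w.w, hf)                   # (N, HW, C)
            return F.transpose(ctx, (0, 2, 1))        # (N, C, HW)
        hf = F.relu(self.h_transform(f.f))            # (N, K, C_ctx)
        n, k, c = hf.shape
        # per-(sample, region) channel normalization via a groups=1 GroupNorm
        # over each prototype vector
        hf = F.reshape(self.h_norm(F.reshape(hf, (n * k, c, 1, 1))), (n, k, c))
        ctx = F.matmul(w.w, hf)                       # (N, HW, C_ctx)
        return F.transpose(ctx, (0, 2, 1))

    def augmented_segmentation(self, x: PixelRepresentations,
                               context: Tensor) -> AugmentedRepresentation:
        """Concatenate contextual and pixel representations -> seg logits."""
        feats = x.features
        n, c, h, w = feats.shape
        ctx_map = F.reshape(context, (n, context.shape[1], h, w))
        if not self.cfg.identity_transforms:
            ctx_map = F.relu(self.delta_conv(ctx_map))
        aug = F.concat([ctx_map, feats], axis=1)
        seg_logits = self.aug_conv(aug)
        return AugmentedRepresentation(features=aug, seg_logits=seg_logits)

    def forward(self, x: PixelRepresentations):
        d = self.soft_regions(x)
        f = self.region_representations(x, d)
        w = self.pixel_region_relation(x, f)
        ctx = self.contextual_representation(w, f)
        aug = self.augmented_segmentation(x, ctx)
        return d, f, w, aug


def predict_mask(seg_logits: np.ndarray, min_area_frac: float = 0.0) -> np.ndarray:
    """Argmax over region channels; ties break toward the lower index
    (background) because argmax returns the first maximum.

    ``min_area_frac`` > 0 removes connected foreground components smaller
    than that fraction of the image (standard speckle-robust cleanup: a
    handful of stray pixels otherwise turns a correctly-empty prediction
    into Dice 0 against an empty truth).
    """
    masks = np.argmax(seg_logits, axis=1).astype(np.uint8)
    if min_area_frac > 0:
        from skimage import morphology
        min_px = int(np.ceil(min_area_frac * masks[0].size))
        if min_px > 1:
            cleaned = [morphology.remove_small_objects(
                m.astype(bool), max_size=min_px - 1) for m in masks]
            masks = np.stack(cleaned).astype(np.uint8)
    return masks
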