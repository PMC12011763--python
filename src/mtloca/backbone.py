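"""Three-level residual encoder-decoder (Res-UNet) backbone.

Produces full-resolution per-pixel feature maps that feed both the
segmentation head (object contextual attention) and the classifier.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["BackboneConfig", "PixelRepresentations", "ResBlock", "ResUNet"]


@dataclasses.dataclass(frozen=True)
class BackboneConfig:
    depth: int = 3
    base_channels: int = 32
    groupnorm_groups: int = 8
    in_channels: int = 2

    def __post_init__(self):
        if self.depth != 3:
            raise ValueError("backbone depth is fixed at 3")
        if self.base_channels % self.groupnorm_groups:
            raise ValueError("base_channels must be divisible by groupnorm_groups")

    @property
    def feature_channels(self) -> int:
        """Width of the pixel-representation map both heads consume."""
        return 2 * self.base_channels


@dataclasses.dataclass
class PixelRepresentations:
    """Per-pixel feature vectors x_i at a declared spatial stride."""
    features: Tensor  # (N, C_f, H_f, W_f)
    stride: int = 1

    def validate(self):
        if not np.all(np.isfinite(self.features.data)):
            raise FloatingPointError("non-finite pixel representations")


class ResBlock(nn.Module):
    """Conv3x3 + GroupNorm with an identity (or 1x1-projected) shortcut."""

    def __init__(self, cin: int, cout: int, groups: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(cin, cout, 3, rng)
        self.norm = nn.GroupNorm(groups, cout)
        self.proj = nn.Conv2d(cin, cout, 1, rng, bias=False) if cin != cout else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(F.add(self.norm(self.conv(x)), self.proj(x)))


class ResUNet(nn.Module):
    """Encoder (conv/GN + maxpool) x3, bottleneck, mirrored decoder
    (upsample + conv/GN) x3 with skip concatenation, then a fusing block.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        b, g = cfg.base_channels, cfg.groupnorm_groups
        widths = [b, 2 * b, 4 * b]
        self.stem = ResBlock(cfg.in_channels, b, g, rng)
        self.enc = [ResBlock(widths[i], widths[i + 1], g, rng) for i in range(2)]
        self.bottleneck = ResBlock(widths[2], 8 * b, g, rng)
        self.dec = [
            ResBlock(8 * b + widths[2], widths[2], g, rng),
            ResBlock(widths[2] + widths[1], widths[1], g, rng),
            ResBlock(widths[1] + widths[0], widths[0], g, rng),
        ]
        self.fuse = ResBlock(b, cfg.feature_channels, g, rng)

    def forward(self, x: Tensor, return_intermediates: bool = False):
        e0 = self.stem(x)                     # (b, H, W)
        p0 = F.maxpool2d(e0)
        e1 = self.enc[0](p0)                  # (2b, H/2, W/2)
        p1 = F.maxpool2d(e1)
        e2 = self.enc[1](p1)                  # (4b, H/4, W/4)
        p2 = F.maxpool2d(e2)
        bott = self.bottleneck(p2)            # (8b, H/8, W/8)
        d2 = self.dec[0](F.concat([F.upsample2x(bott), e2], axis=1))
        d1 = self.dec[1](F.concat([F.upsample2x(d2), e1], axis=1))
        d0 = self.dec[2](F.concat([F.upsample2x(d1), e0], axis=1))
        feats = self.fuse(d0)                 # (2b, H, W)
        reps = PixelRepresentations(features=feats, stride=1)
        if return_intermediates:
            return reps, {"bottleneck": bott, "decoder_out": d0,
                          "encoder": [e0, e1, e2]}
        return reps

    def summary(self) -> str:
        lines = [f"ResUNet(base={self.cfg.base_channels}, "
                 f"in={self.cfg.in_channels}, features={self.cfg.feature_channels})"]
        for name, p in self.named_parameters().items():
            lines.append(f"  {name:40s} {str(p.data.shape):20s} {p.data.size}")
        lines.append(f"  total parameters: {self.num_parameters()}")
        return "\n".join(lines)
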