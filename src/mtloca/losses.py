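"""Combined multi-task loss: total = alpha * L_soft + L_aug + L_c.

All three terms are mean cross-entropies: L_soft on the coarse soft-region
logits, L_aug on the augmented-representation segmentation logits, and L_c
on the class logits. alpha defaults to 0.4.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor

DEFAULT_ALPHA = 0.4

__all__ = ["DEFAULT_ALPHA", "LossBreakdown", "combined_loss"]


@dataclasses.dataclass
class LossBreakdown:
    l_soft: float
    l_aug: float
    l_c: float
    alpha: float

    @property
    def l_s(self) -> float:
        return self.alpha * self.l_soft + self.l_aug

    @property
    def total(self) -> float:
        return self.l_s + self.l_c

    def to_dict(self) -> dict:
        return {"l_soft": self.l_soft, "l_aug": self.l_aug, "l_c": self.l_c,
                "l_s": self.l_s, "l_c_": self.l_c, "alpha": self.alpha,
                "total": self.total}


def _validate_targets(mask_target: np.ndarray, label_target: np.ndarray,
                      num_regions: int, num_classes: int):
    m = np.asarray(mask_target)
    if not np.isin(m, np.arange(num_regions)).all():
        raise ValueError(f"mask targets must lie in [0, {num_regions})")
    t = np.asarray(label_target)
    if not np.isin(t, np.arange(num_classes)).all():
        raise ValueError(f"class targets must lie in [0, {num_classes})")


def combined_loss(soft_logits: Tensor | None, aug_logits: Tensor,
                  mask_target: np.ndarray, class_logits: Tensor,
                  label_target: np.ndarray, alpha: float = DEFAULT_ALPHA
                  ) -> tuple[Tensor, LossBreakdown]:
    """Differentiable total loss plus its numeric breakdown.

    ``soft_logits`` may be None (no-OCA variant); l_soft is then 0 and the
    segmentation loss reduces to l_aug alone.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    _validate_targets(mask_target, label_target, aug_logits.shape[1],
                      class_logits.shape[1])
    l_aug = F.softmax_cross_entropy(aug_logits, mask_target)
    l_c = F.softmax_cross_entropy(class_logits, label_target)
    if soft_logits is not None:
        l_soft = F.softmax_cross_entropy(soft_logits, mask_target)
        total = F.add(F.add(F.mul(l_soft, alpha), l_aug), l_c)
        soft_val = float(l_soft.data)
    else:
        total = F.add(l_aug, l_c)
        soft_val = 0.0
    breakdown = LossBreakdown(l_soft=soft_val, l_aug=float(l_aug.data),
                              l_c=float(l_c.data), alpha=alpha)
    for name, val in (("l_soft", breakdown.l_soft), ("l_aug", breakdown.l_aug),
                      ("l_c", breakdown.l_c)):
        if not np.isfinite(val):
            raise FloatingPointError(f"loss component {name} is non-finite")
    return total, breakdown
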