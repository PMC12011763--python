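"""Grad-CAM heatmaps for the classification head.

Target layer is the backbone's output feature map (the representation both
heads consume): channel weights are the spatially averaged gradients of the
chosen class score, the map is their ReLU-ed weighted sum, upsampled to the
input size and normalized by its maximum.
"""
from __future__ import annotations

import numpy as np
from skimage import transform

from .model import MTLOCA
from .nn.tensor import Tensor
from .preprocess import TARGET_SIZE, ModelInput

__all__ = ["grad_cam"]


def grad_cam(model: MTLOCA, mi: ModelInput, target_class: int) -> np.ndarray:
    """128x128 heatmap in [0, 1] for ``target_class`` on one input."""
    if not 0 <= target_class < model.cfg.num_classes:
        raise ValueError(f"target_class {target_class} out of range")
    x = Tensor(mi.channels[None].astype(np.float32))
    out = model(x)
    model.zero_grad()
    target = out.cls_features  # activation map feeding the classifier
    target.grad = None
    onehot = np.zeros_like(out.class_logits.data)
    onehot[0, target_class] = 1.0
    score = (out.class_logits * Tensor(onehot)).sum()
    score.backward()
    grads = target.grad
    if grads is None or not np.any(grads):
        return np.zeros((TARGET_SIZE, TARGET_SIZE), dtype=np.float64)
    weights = grads[0].mean(axis=(1, 2))                     # (C,)
    cam = np.maximum((weights[:, None, None] * target.data[0]).sum(axis=0), 0.0)
    if cam.shape != (TARGET_SIZE, TARGET_SIZE):
        cam = transform.resize(cam, (TARGET_SIZE, TARGET_SIZE), order=1,
                               preserve_range=True)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam
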