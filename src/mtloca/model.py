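"""Full multi-task model: backbone + OCA segmentation head + MLP classifier.

Three wiring variants mirror the ablation arms:

- ``no_oca``            backbone features -> plain 1x1 seg head; classifier
                        on backbone features.
- ``cls_from_oca``      OCA seg head; classifier on the OCA-augmented
                        representation.
- ``cls_from_backbone`` OCA seg head; classifier on backbone features
                        (the proposed configuration).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .backbone import BackboneConfig, PixelRepresentations, ResUNet
from .nn import functional as F
from .nn.tensor import Tensor
from .oca import OCAConfig, OCAModule, predict_mask
from .phantom import CLASSES

VARIANTS = ("no_oca", "cls_from_oca", "cls_from_backbone")

__all__ = ["VARIANTS", "ModelConfig", "ModelOutput", "MTLOCA",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = dataclasses.field(default_factory=BackboneConfig)
    oca: OCAConfig = dataclasses.field(default_factory=OCAConfig)
    variant: str = "cls_from_backbone"
    mlp_hidden: int = 128
    num_classes: int = 3

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclasses.dataclass
class ModelOutput:
    features: Tensor            # backbone pixel representations
    seg_logits: Tensor          # (N, K, H, W) final segmentation scores
    class_logits: Tensor        # (N, 3) ordered (normal, benign, malignant)
    soft_logits: Tensor | None  # (N, K, H, W) coarse-mask logits (None w/o OCA)
    cls_features: Tensor        # map the classifier pools over (Grad-CAM target)

    def predicted_masks(self) -> np.ndarray:
        return predict_mask(self.seg_logits.data)

    def predicted_labels(self) -> np.ndarray:
        return np.argmax(self.class_logits.data, axis=1)


class Classifier(nn.Module):
    """Global average pooling + 2-layer MLP ending in one neuron per class."""

    def __init__(self, in_channels: int, hidden: int, num_classes: int,
                 rng: np.random.Generator):
        self.fc1 = nn.Linear(in_channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, num_classes, rng)

    def forward(self, feature_map: Tensor) -> Tensor:
        pooled = F.global_avg_pool(feature_map)
        return self.fc2(F.relu(self.fc1(pooled)))


class MTLOCA(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.backbone = ResUNet(cfg.backbone, rng)
        cf = cfg.backbone.feature_channels
        if cfg.variant == "no_oca":
            self.oca = None
            self.seg_head = nn.Conv2d(cf, cfg.oca.num_regions, 1, rng)
            cls_in = cf
        else:
            self.oca = OCAModule(cf, cfg.oca, rng)
            self.seg_head = None
            cls_in = cf + self.oca.context_channels if cfg.variant == "cls_from_oca" else cf
        self.classifier = Classifier(cls_in, cfg.mlp_hidden, cfg.num_classes, rng)

    def forward(self, x: Tensor) -> ModelOutput:
        reps = self.backbone(x)
        if self.cfg.variant == "no_oca":
            seg_logits = self.seg_head(reps.features)
            soft_logits = None
            cls_features = reps.features
        else:
            d, f, w, aug = self.oca(reps)
            seg_logits = aug.seg_logits
            soft_logits = d.logits
            cls_features = aug.features if self.cfg.variant == "cls_from_oca" else reps.features
        class_logits = self.classifier(cls_features)
        return ModelOutput(features=reps.features, seg_logits=seg_logits,
                           class_logits=class_logits, soft_logits=soft_logits,
                           cls_features=cls_features)

    @staticmethod
    def batch_tensor(model_inputs, requires_grad: bool = False) -> Tensor:
        arr = np.stack([mi.channels for mi in model_inputs]).astype(np.float32)
        return Tensor(arr, requires_grad=requires_grad)


def _config_to_dict(cfg: ModelConfig) -> dict:
    return {
        "backbone": dataclasses.asdict(cfg.backbone),
        "oca": dataclasses.asdict(cfg.oca),
        "variant": cfg.variant,
        "mlp_hidden": cfg.mlp_hidden,
        "num_classes": cfg.num_classes,
    }


def _config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(backbone=BackboneConfig(**d["backbone"]),
                       oca=OCAConfig(**d["oca"]),
                       variant=d["variant"], mlp_hidden=d["mlp_hidden"],
                       num_classes=d["num_classes"])


def save_checkpoint(model: MTLOCA, path: str | Path):
    """Single-file .npz checkpoint with the config embedded."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(_config_to_dict(model.cfg)))
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> MTLOCA:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        cfg = _config_from_dict(json.loads(str(z["config_json"])))
        model = MTLOCA(cfg, rng=np.random.default_rng(0))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model


def label_name(index: int) -> str:
    return CLASSES[index]
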