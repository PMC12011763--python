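"""Evaluation metrics: Dice/IoU, per-class precision / sensitivity /
specificity / F1, accuracy, confusion matrices, and report serialization.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import CLASSES

__all__ = [
    "dice_iou", "confusion_matrix", "classification_metrics",
    "f1_from_precision_sensitivity", "MetricsReport", "render_confusion_png",
]


def dice_iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[float, float]:
    """Overlap scores between binary masks.

    Both-empty pairs score (1.0, 1.0): a correctly predicted lesion-free
    image is a perfect segmentation.
    """
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    if not (set(np.unique(p)) <= {0, 1} and set(np.unique(t)) <= {0, 1}):
        raise ValueError("masks must be binary")
    p = p.astype(bool)
    t = t.astype(bool)
    inter = np.logical_and(p, t).sum()
    psum, tsum = p.sum(), t.sum()
    union = psum + tsum - inter
    if psum + tsum == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (psum + tsum)
    iou = inter / union
    return float(dice), float(iou)


def confusion_matrix(true_labels, pred_labels, num_classes: int = 3) -> np.ndarray:
    """Counts with rows = truth, columns = prediction."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have identical shape")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def f1_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision < 0 or sensitivity < 0:
        raise ValueError("precision/sensitivity must be non-negative")
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def classification_metrics(confusion: np.ndarray) -> dict:
    """One-vs-rest rates per class plus overall accuracy.

    Returns {"accuracy": float, "per_class": {label: {precision, sensitivity,
    specificity, f1}}}. Undefined ratios (zero denominators) come back as NaN.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any() or not np.issubdtype(cm.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integers")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix: metrics undefined")
    k = cm.shape[0]
    per_class = {}
    for i in range(k):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else float("nan")
        sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        specificity = tn / (tn + fp) if tn + fp else float("nan")
        if np.isnan(precision) or np.isnan(sensitivity):
            f1 = float("nan")
        else:
            f1 = f1_from_precision_sensitivity(precision, sensitivity)
        name = CLASSES[i] if k == len(CLASSES) else str(i)
        per_class[name] = {"precision": float(precision),
                           "sensitivity": float(sensitivity),
                           "specificity": float(specificity), "f1": float(f1)}
    return {"accuracy": float(np.trace(cm) / total), "per_class": per_class}


@dataclasses.dataclass
class MetricsReport:
    """Per-fold or pooled evaluation summary (percentages for dice/iou/acc)."""
    dice: float
    iou: float
    acc: float
    per_class: dict
    confusion: np.ndarray
    n_samples: int

    @classmethod
    def from_results(cls, dices, ious, true_labels, pred_labels) -> "MetricsReport":
        cm = confusion_matrix(true_labels, pred_labels)
        stats = classification_metrics(cm)
        return cls(dice=100.0 * float(np.mean(dices)),
                   iou=100.0 * float(np.mean(ious)),
                   acc=100.0 * stats["accuracy"],
                   per_class=stats["per_class"], confusion=cm,
                   n_samples=len(true_labels))

    def validate(self):
        if self.confusion.sum() != self.n_samples:
            raise ValueError("confusion entries must sum to the sample count")
        if not 0 <= self.acc <= 100:
            raise ValueError("accuracy out of range")

    def to_dict(self) -> dict:
        return {"dice": self.dice, "iou": self.iou, "acc": self.acc,
                "per_class": self.per_class,
                "confusion": self.confusion.tolist(),
                "n_samples": self.n_samples}

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path):
        rows = []
        for label, stats in self.per_class.items():
            rows.append({"label": label, **stats})
        df = pd.DataFrame(rows)
        df.insert(0, "dice_pct", self.dice)
        df.insert(1, "iou_pct", self.iou)
        df.insert(2, "acc_pct", self.acc)
        df.to_csv(path, index=False)


def render_confusion_png(confusion: np.ndarray, path: str | Path,
                         class_names=CLASSES):
    """Confusion-matrix heatmap (truth rows, prediction columns)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(confusion, cmap="Blues")
    k = confusion.shape[0]
    ax.set_xticks(range(k), class_names[:k])
    ax.set_yticks(range(k), class_names[:k])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(confusion[i, j]), ha="center", va="center")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
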