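"""Training/evaluation orchestration: stratified 5-fold CV, the Adam
training protocol, the three ablation arms, and report pooling.

Two scale profiles exist: ``full`` mirrors the reference protocol
(400 epochs, batch 16, base width 32, 128x128); ``desk`` shrinks the width,
epoch count and training resolution so the whole ablation suite runs on one
CPU core in minutes.
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import BackboneConfig
from .losses import DEFAULT_ALPHA, combined_loss
from .metrics import MetricsReport, confusion_matrix, dice_iou
from .model import MTLOCA, VARIANTS, ModelConfig, load_checkpoint, save_checkpoint
from .nn import Adam
from .nn.tensor import Tensor
from .oca import OCAConfig, predict_mask
from .phantom import CLASSES, LabeledSample
from .preprocess import (AugmentConfig, DerivativeConfig, ModelInput, augment,
                         build_model_input)

__all__ = ["TrainConfig", "FoldPlan", "make_folds", "train_fold", "train",
           "evaluate", "evaluate_fold", "run_ablation", "ablation_table",
           "load_models", "prepare_inputs", "NaNLossError"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    batch_size: int = 16
    learning_rate: float = 1e-3
    folds: int = 5
    seed: int = 0
    variant: str = "cls_from_backbone"
    alpha: float = DEFAULT_ALPHA
    scale: str = "full"           # "full" | "desk"
    base_channels: int | None = None   # override profile width
    region_weight_norm: str = "pixels"  # region-aggregation normalization
    #: evaluation-time cleanup: drop predicted components smaller than
    #: this fraction of the image (well below any generated lesion)
    min_lesion_area_frac: float = 0.002
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    derivative: DerivativeConfig = dataclasses.field(default_factory=DerivativeConfig)
    # deliberately absent per the reference protocol; exposed, default off
    weight_decay: float = 0.0
    lr_schedule: str | None = None
    early_stopping: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.scale not in ("full", "desk"):
            raise ValueError("scale must be 'full' or 'desk'")
        if self.lr_schedule is not None or self.early_stopping:
            raise NotImplementedError("lr schedules / early stopping are config "
                                      "placeholders and intentionally unimplemented")

    @property
    def train_size(self) -> int:
        """Spatial resolution the network trains/evaluates at."""
        return 64 if self.scale == "desk" else 128

    def model_config(self) -> ModelConfig:
        if self.scale == "desk":
            base = self.base_channels or 8
            oca = OCAConfig(key_channels=16, context_channels=16,
                            groupnorm_groups=8,
                            region_weight_norm=self.region_weight_norm)
            hidden = 32
        else:
            base = self.base_channels or 32
            oca = OCAConfig(region_weight_norm=self.region_weight_norm)
            hidden = 128
        return ModelConfig(backbone=BackboneConfig(base_channels=base),
                           oca=oca, variant=self.variant, mlp_hidden=hidden)


@dataclasses.dataclass
class FoldPlan:
    folds: list[dict]            # [{"train": [ids], "val": [ids]}]
    stratification: dict         # class -> per-fold validation counts

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(manifest: pd.DataFrame, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold partition of the manifest, deterministic in seed."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    strat: dict[str, list[int]] = {}
    for label in sorted(manifest["label"].unique()):
        ids = sorted(manifest.loc[manifest["label"] == label, "id"])
        if len(ids) < k:
            raise ValueError(f"class {label!r} has {len(ids)} samples, "
                             f"fewer than k={k}: cannot stratify")
        order = rng.permutation(len(ids))
        counts = [0] * k
        for pos, idx in enumerate(order):
            fold = pos % k
            assignments[ids[idx]] = fold
            counts[fold] += 1
        strat[label] = counts
    all_ids = list(manifest["id"])
    folds = []
    for f in range(k):
        val = [i for i in all_ids if assignments[i] == f]
        tr = [i for i in all_ids if assignments[i] != f]
        folds.append({"train": tr, "val": val})
    return FoldPlan(folds=folds, stratification=strat)


def _downsample_input(mi: ModelInput, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Average-pool channels / nearest-sample the mask down to size x size."""
    c, h, w = mi.channels.shape
    if h == size:
        return mi.channels, mi.mask
    f = h // size
    ch = mi.channels.reshape(c, size, f, size, f).mean(axis=(2, 4))
    mask = mi.mask[::f, ::f]
    return ch.astype(np.float32), np.ascontiguousarray(mask)


def prepare_inputs(samples: list[LabeledSample],
                   cfg: TrainConfig) -> dict[str, ModelInput]:
    return {s.id: build_model_input(s, cfg.derivative) for s in samples}


def _batch_arrays(inputs: list[ModelInput], cfg: TrainConfig,
                  rng: np.random.Generator | None):
    """Optionally augment, downsample to the training resolution, stack."""
    chans, masks, labels = [], [], []
    for mi in inputs:
        if rng is not None:
            mi = augment(mi, cfg.augment, rng)
        ch, mask = _downsample_input(mi, cfg.train_size)
        chans.append(ch)
        masks.append(mask)
        labels.append(mi.label)
    return (np.stack(chans).astype(np.float32),
            np.stack(masks).astype(np.int64), np.asarray(labels))


class NaNLossError(RuntimeError):
    pass


def train_fold(cfg: TrainConfig, inputs: dict[str, ModelInput],
               train_ids: list[str], fold_index: int = 0,
               log_path: str | Path | None = None) -> tuple[MTLOCA, list[dict]]:
    """Train one model on one fold's training ids; returns model + epoch log."""
    seed_seq = np.random.SeedSequence([cfg.seed, fold_index])
    init_rng, order_rng, aug_rng = [np.random.default_rng(s)
                                    for s in seed_seq.spawn(3)]
    model = MTLOCA(cfg.model_config(), rng=init_rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    log: list[dict] = []
    ids = list(train_ids)
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(len(ids))
        epoch_terms = []
        t0 = time.time()
        for start in range(0, len(ids), cfg.batch_size):
            batch_ids = [ids[i] for i in order[start:start + cfg.batch_size]]
            x, masks, labels = _batch_arrays([inputs[i] for i in batch_ids],
                                             cfg, aug_rng)
            opt.zero_grad()
            out = model(Tensor(x))
            try:
                total, breakdown = combined_loss(
                    out.soft_logits, out.seg_logits, masks,
                    out.class_logits, labels, alpha=cfg.alpha)
            except FloatingPointError as exc:
                raise NaNLossError(
                    f"fold {fold_index} epoch {epoch}: {exc}") from exc
            total.backward()
            opt.step()
            epoch_terms.append(breakdown)
        entry = {
            "fold": fold_index, "epoch": epoch,
            "l_soft": float(np.mean([b.l_soft for b in epoch_terms])),
            "l_aug": float(np.mean([b.l_aug for b in epoch_terms])),
            "l_c": float(np.mean([b.l_c for b in epoch_terms])),
            "total": float(np.mean([b.total for b in epoch_terms])),
            "seconds": time.time() - t0,
            "train_ids": sorted(ids) if epoch == 0 else None,
        }
        log.append(entry)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
    return model, log


def evaluate_fold(model: MTLOCA, cfg: TrainConfig,
                  inputs: dict[str, ModelInput], val_ids: list[str]
                  ) -> MetricsReport:
    """Validation-fold metrics: per-image Dice/IoU + classification counts."""
    dices, ious, truth, preds = [], [], [], []
    bs = max(cfg.batch_size, 1)
    for start in range(0, len(val_ids), bs):
        chunk = [inputs[i] for i in val_ids[start:start + bs]]
        x, masks, labels = _batch_arrays(chunk, cfg, rng=None)
        out = model(Tensor(x))
        pred_masks = predict_mask(out.seg_logits.data,
                                  min_area_frac=cfg.min_lesion_area_frac)
        pred_labels = out.predicted_labels()
        for i in range(len(chunk)):
            d, j = dice_iou(pred_masks[i], masks[i])
            dices.append(d)
            ious.append(j)
        truth.extend(labels.tolist())
        preds.extend(pred_labels.tolist())
    report = MetricsReport.from_results(dices, ious, truth, preds)
    report.validate()
    return report


def train(cfg: TrainConfig, samples: list[LabeledSample],
          manifest: pd.DataFrame, out_dir: str | Path | None = None,
          folds: list[int] | None = None
          ) -> tuple[FoldPlan, dict[int, MTLOCA], list[dict]]:
    """Cross-validated training; optionally writes checkpoints + JSONL log."""
    plan = make_folds(manifest, cfg.folds, cfg.seed)
    inputs = prepare_inputs(samples, cfg)
    models: dict[int, MTLOCA] = {}
    full_log: list[dict] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for f in folds if folds is not None else range(plan.k):
        log_path = out / "train_log.jsonl" if out is not None else None
        model, log = train_fold(cfg, inputs, plan.folds[f]["train"],
                                fold_index=f, log_path=log_path)
        models[f] = model
        full_log.extend(log)
        if out is not None:
            save_checkpoint(model, out / f"fold{f}.npz")
    return plan, models, full_log


def evaluate(cfg: TrainConfig, models: dict[int, MTLOCA], plan: FoldPlan,
             inputs: dict[str, ModelInput]) -> dict:
    """Per-fold reports plus a pooled report.

    Pooled confusion = sum of fold confusions; pooled Dice/IoU = mean over
    every evaluated image; a per-fold mean summary is emitted alongside.
    """
    fold_reports = {}
    dices, ious, truth, preds = [], [], [], []
    for f, model in models.items():
        val_ids = plan.folds[f]["val"]
        rep = evaluate_fold(model, cfg, inputs, val_ids)
        fold_reports[f] = rep
        # recompute raw per-image stats for pooling
        x, masks, labels = _batch_arrays([inputs[i] for i in val_ids], cfg, None)
        out = model(Tensor(x))
        pm = predict_mask(out.seg_logits.data,
                          min_area_frac=cfg.min_lesion_area_frac)
        for i in range(len(val_ids)):
            d, j = dice_iou(pm[i], masks[i])
            dices.append(d)
            ious.append(j)
        truth.extend(labels.tolist())
        preds.extend(out.predicted_labels().tolist())
    pooled = MetricsReport.from_results(dices, ious, truth, preds)
    pooled.validate()
    fold_mean = {
        "dice": float(np.mean([r.dice for r in fold_reports.values()])),
        "iou": float(np.mean([r.iou for r in fold_reports.values()])),
        "acc": float(np.mean([r.acc for r in fold_reports.values()])),
    }
    return {"folds": fold_reports, "pooled": pooled, "fold_mean": fold_mean}


def load_models(ckpt_dir: str | Path, plan: FoldPlan) -> dict[int, MTLOCA]:
    models = {}
    for f in range(plan.k):
        path = Path(ckpt_dir) / f"fold{f}.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing checkpoint for fold {f}: {path}")
        models[f] = load_checkpoint(path)
    return models


def run_ablation(base_cfg: TrainConfig, samples: list[LabeledSample],
                 manifest: pd.DataFrame, folds: list[int] | None = None
                 ) -> dict[str, dict]:
    """Three variants on identical data, seed, and budget."""
    results = {}
    for variant in VARIANTS:
        cfg = dataclasses.replace(base_cfg, variant=variant)
        plan, models, _ = train(cfg, samples, manifest, folds=folds)
        inputs = prepare_inputs(samples, cfg)
        results[variant] = evaluate(cfg, models, plan, inputs)
    return results


def ablation_table(results: dict[str, dict]) -> pd.DataFrame:
    rows = []
    names = {"no_oca": "Model without OCA",
             "cls_from_oca": "Model with OCA, classification based on OCA",
             "cls_from_backbone": "Model with OCA, classification based on backbone"}
    for variant in VARIANTS:
        pooled = results[variant]["pooled"]
        rows.append({"configuration": names[variant],
                     "dice_pct": pooled.dice, "acc_pct": pooled.acc})
    return pd.DataFrame(rows)
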