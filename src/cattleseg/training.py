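"""Seeded training loop, evaluation, and the ablation harness.

The schedule is SGD with momentum on per-pixel cross-entropy, with the
poly learning-rate decay lr = lr0·(1 − iter/max_iter)^power applied per
iteration. Defaults mirror the reference experiment protocol (480×480
inputs, batch 4, lr0 0.01, momentum 0.9, 60 epochs); every field is
overridable for CPU-scale runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .data.scenes import LabeledScene
from .exceptions import ConfigurationError, DataError, TrainingError
from .metrics import ConfusionMatrix, MetricsReport, compute_report
from .model import ModelVariant, NetworkWidths, SegmentationNetwork, build_model
from .nn import functional as F

__all__ = ["TrainConfig", "poly_lr", "train", "evaluate", "run_ablation",
           "TABLE_COLUMNS"]

TABLE_COLUMNS = ["PA", "MPA", "MIoU", "CPA(Cow)", "CPA(Beef)",
                 "IoU(Cow)", "IoU(Beef)"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run."""

    input_size: int = 480
    batch_size: int = 4
    lr0: float = 0.01
    momentum: float = 0.9
    epochs: int = 60
    poly_power: float = 0.9
    seed: int = 0
    loss: str = "cross_entropy"
    augment_hflip: bool = True
    weight_decay: float = 0.0
    checkpoint_every: int = 0        # epochs; 0 = only implicit final state

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be positive")
        if self.lr0 <= 0 or self.poly_power <= 0:
            raise ConfigurationError("lr0 and poly_power must be positive")
        if self.loss != "cross_entropy":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")


def poly_lr(iteration: int, max_iterations: int, config: TrainConfig) -> float:
    """Poly decay: lr0·(1 − iteration/max_iterations)^power."""
    if max_iterations <= 0:
        raise ConfigurationError("max_iterations must be positive")
    if not 0 <= iteration <= max_iterations:
        raise ConfigurationError(
            f"iteration {iteration} outside [0, {max_iterations}]")
    return config.lr0 * (1.0 - iteration / max_iterations) ** config.poly_power


def _stack_scenes(scenes: Sequence[LabeledScene]):
    shapes = {s.shape for s in scenes}
    if len(shapes) != 1:
        raise DataError(f"scenes in a batchable set must share one size, got {shapes}")
    images = np.stack([s.image for s in scenes])
    masks = np.stack([s.mask for s in scenes])
    return images, masks


def train(model: SegmentationNetwork, train_set: Sequence[LabeledScene],
          config: TrainConfig, checkpoint_dir=None):
    """Train in place; returns ``(model, loss_trace)``.

    Deterministic given ``config.seed``: data order, horizontal-flip
    augmentation and the schedule all derive from it. ``loss_trace`` is
    one (iteration, lr, loss) triple per optimisation step.
    """
    scenes = list(train_set)
    if not scenes:
        raise DataError("training set is empty")
    images, masks = _stack_scenes(scenes)
    nc = model.variant.num_classes
    if masks.max() >= nc:
        raise DataError(f"mask labels reach {masks.max()} but the model has "
                        f"{nc} classes")
    rng = np.random.default_rng(config.seed)
    n = len(scenes)
    batches_per_epoch = (n + config.batch_size - 1) // config.batch_size
    max_iter = config.epochs * batches_per_epoch
    opt = nn.SGD(list(model.parameters()), lr=config.lr0,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    model.train()
    trace: List[dict] = []
    it = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for b in range(batches_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            x = images[idx]
            y = masks[idx]
            if config.augment_hflip:
                flip = rng.random(len(idx)) < 0.5
                if flip.any():
                    x = x.copy()
                    y = y.copy()
                    x[flip] = x[flip, :, ::-1]
                    y[flip] = y[flip, :, ::-1]
            opt.lr = poly_lr(it, max_iter, config)
            opt.zero_grad()
            logits = model.forward(x)
            loss = F.softmax_cross_entropy(logits, y)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise TrainingError(
                    f"non-finite loss at iteration {it} (lr={opt.lr:.5g}, "
                    f"epoch={epoch}, batch scenes={[scenes[i].scene_id for i in idx]})")
            loss.backward()
            opt.step()
            trace.append({"iteration": it, "epoch": epoch,
                          "lr": opt.lr, "loss": loss_val})
            it += 1
        if checkpoint_dir and config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            from .model import save_checkpoint
            from pathlib import Path
            p = Path(checkpoint_dir)
            p.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, p / f"epoch{epoch + 1:03d}.npz")
    model.eval()
    return model, trace


def save_loss_trace(trace: Sequence[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["iteration", "epoch", "lr", "loss"])
        writer.writeheader()
        writer.writerows(trace)


def evaluate(model, test_set: Sequence[LabeledScene],
             cpa_mode: str = "precision", num_classes: Optional[int] = None,
             batch_size: int = 4) -> MetricsReport:
    """Accumulate one confusion matrix over a test set at native
    resolution and score it.

    ``model`` only needs a ``predict(images) -> masks`` method, so metric
    parity can be checked against stub predictors and saved masks.
    """
    scenes = list(test_set)
    if not scenes:
        raise DataError("evaluation set is empty")
    nc = num_classes or getattr(getattr(model, "variant", None), "num_classes", 3)
    cm = ConfusionMatrix(nc)
    by_shape: Dict[tuple, List[LabeledScene]] = {}
    for s in scenes:
        by_shape.setdefault(s.shape, []).append(s)
    for group in by_shape.values():
        images, masks = _stack_scenes(group)
        pred = model.predict(images) if len(images) > 1 or images.ndim == 4 \
            else model.predict(images[0])[None]
        cm.add(masks, pred)
    return compute_report(cm, cpa_mode=cpa_mode)


def run_ablation(variants: Sequence[ModelVariant],
                 train_set: Sequence[LabeledScene],
                 eval_sets: Dict[str, Sequence[LabeledScene]],
                 config: TrainConfig,
                 widths: Optional[NetworkWidths] = None) -> pd.DataFrame:
    """Train and evaluate each variant under identical seed and data.

    Returns one row per (variant, evaluation set) with the customary
    seven metric columns. A failing variant yields NaN rows annotated
    with the error and does not stop the remaining variants.
    """
    if not variants:
        raise ConfigurationError("run_ablation needs at least one variant")
    rows = []
    for variant in variants:
        try:
            model = build_model(variant, widths=widths, seed=config.seed)
            model, _ = train(model, train_set, config)
            for set_name, scenes in eval_sets.items():
                report = evaluate(model, scenes)
                row = {"model": variant.name, "eval_set": set_name,
                       **{c: report.table_row().get(c, np.nan) for c in TABLE_COLUMNS},
                       "error": ""}
                rows.append(row)
        except Exception as e:  # noqa: BLE001 - harness must keep going
            for set_name in eval_sets:
                rows.append({"model": variant.name, "eval_set": set_name,
                             **{c: np.nan for c in TABLE_COLUMNS},
                             "error": f"{type(e).__name__}: {e}"})
    return pd.DataFrame(rows)
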