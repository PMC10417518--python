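"""Confusion-matrix accumulation and the five segmentation statistics.

All metrics derive from one NC×NC pixel-count table with ground truth on
rows and predictions on columns. With TP/FP/FN/TN read off that table per
class, the statistics are

* PA — pixel accuracy, (TP+TN)/(TP+FP+FN+TN) = trace / total;
* CPA — class pixel accuracy, TP/(TP+FP) per class (i.e. the precision
  form; a recall form TP/(TP+FN) is available via ``mode="recall"``);
* MPA — mean of the defined per-class CPAs;
* IoU — TP/(TP+FP+FN) per class;
* MIoU — mean of the defined per-class IoUs.

A class absent from both truth and prediction has an undefined CPA/IoU;
such classes are reported as NaN and excluded from the means, and the
report records which classes were excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import DataError, UndefinedMetricError

__all__ = ["ConfusionMatrix", "MetricsReport", "accumulate",
           "pixel_accuracy", "class_pixel_accuracy", "mean_pixel_accuracy",
           "iou", "miou", "compute_report", "DEFAULT_CLASS_NAMES"]

DEFAULT_CLASS_NAMES = ("background", "cow", "beef")


class ConfusionMatrix:
    """NC×NC pixel-count table; accumulation is additive over batches."""

    def __init__(self, num_classes: int = 3,
                 class_names: Optional[Sequence[str]] = None):
        if num_classes < 1:
            raise DataError("num_classes must be positive")
        if class_names is None:
            class_names = (DEFAULT_CLASS_NAMES[:num_classes]
                           if num_classes <= 3 else
                           tuple(f"class{i}" for i in range(num_classes)))
        if len(class_names) != num_classes:
            raise DataError("class_names length must equal num_classes")
        self.num_classes = num_classes
        self.class_names = tuple(class_names)
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def add(self, truth_mask: np.ndarray, predicted_mask: np.ndarray,
            ignore_index: Optional[int] = None) -> "ConfusionMatrix":
        """Count each pixel into (truth, prediction); returns self."""
        t = np.asarray(truth_mask)
        p = np.asarray(predicted_mask)
        if t.shape != p.shape:
            raise DataError(
                f"truth mask shape {t.shape} != predicted mask shape {p.shape}")
        t = t.ravel().astype(np.int64)
        p = p.ravel().astype(np.int64)
        if ignore_index is not None:
            keep = t != ignore_index
            t, p = t[keep], p[keep]
        nc = self.num_classes
        if t.size:
            if t.min() < 0 or t.max() >= nc:
                raise DataError(f"truth mask has labels outside [0, {nc})")
            if p.min() < 0 or p.max() >= nc:
                raise DataError(f"predicted mask has labels outside [0, {nc})")
            self.counts += np.bincount(t * nc + p, minlength=nc * nc).reshape(nc, nc)
        return self

    def merge(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise DataError("cannot merge confusion matrices of different sizes")
        self.counts += other.counts
        return self

    def copy(self) -> "ConfusionMatrix":
        cm = ConfusionMatrix(self.num_classes, self.class_names)
        cm.counts = self.counts.copy()
        return cm

    @classmethod
    def from_counts(cls, counts, class_names=None) -> "ConfusionMatrix":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise DataError("counts must be a square matrix")
        if (counts < 0).any():
            raise DataError("counts must be non-negative")
        cm = cls(counts.shape[0], class_names)
        cm.counts = counts.copy()
        return cm


def accumulate(cm: ConfusionMatrix, predicted_mask, truth_mask,
               ignore_index: Optional[int] = None) -> ConfusionMatrix:
    """Functional alias for :meth:`ConfusionMatrix.add`."""
    return cm.add(truth_mask, predicted_mask, ignore_index=ignore_index)


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise UndefinedMetricError("pixel accuracy is undefined on an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


def class_pixel_accuracy(cm: ConfusionMatrix, class_index: int,
                         mode: str = "precision") -> float:
    """Per-class pixel accuracy; NaN when the denominator is zero.

    ``mode="precision"`` (default) is TP/(TP+FP); ``mode="recall"`` is
    TP/(TP+FN).
    """
    tp = cm.counts[class_index, class_index]
    if mode == "precision":
        denom = cm.counts[:, class_index].sum()
    elif mode == "recall":
        denom = cm.counts[class_index, :].sum()
    else:
        raise ValueError(f"mode must be 'precision' or 'recall', got {mode!r}")
    if denom == 0:
        return float("nan")
    return float(tp / denom)


def iou(cm: ConfusionMatrix, class_index: int) -> float:
    """Intersection over union TP/(TP+FP+FN); NaN when the union is empty."""
    tp = cm.counts[class_index, class_index]
    union = (cm.counts[class_index, :].sum()
             + cm.counts[:, class_index].sum() - tp)
    if union == 0:
        return float("nan")
    return float(tp / union)


def _defined_mean(values: Sequence[float], what: str) -> float:
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        raise UndefinedMetricError(f"{what} is undefined: no class has a defined value")
    return float(defined.mean())


def mean_pixel_accuracy(cm: ConfusionMatrix, mode: str = "precision") -> float:
    """Mean of the defined per-class CPAs."""
    return _defined_mean([class_pixel_accuracy(cm, c, mode)
                          for c in range(cm.num_classes)], "MPA")


def miou(cm: ConfusionMatrix) -> float:
    """Mean of the defined per-class IoUs."""
    return _defined_mean([iou(cm, c) for c in range(cm.num_classes)], "MIoU")


@dataclass
class MetricsReport:
    """One evaluation run's statistics, all as fractions in [0, 1].

    ``cpa_per_class``/``iou_per_class`` hold NaN for classes whose metric
    is undefined; those classes are listed in ``undefined_classes`` and
    excluded from the MPA/MIoU means.
    """

    pa: float
    mpa: float
    miou: float
    cpa_per_class: List[float]
    iou_per_class: List[float]
    class_names: List[str]
    cpa_mode: str = "precision"
    undefined_classes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"PA": self.pa, "MPA": self.mpa, "MIoU": self.miou,
                **{f"CPA({n.capitalize()})": v
                   for n, v in zip(self.class_names, self.cpa_per_class)},
                **{f"IoU({n.capitalize()})": v
                   for n, v in zip(self.class_names, self.iou_per_class)},
                "cpa_mode": self.cpa_mode,
                "undefined_classes": list(self.undefined_classes)}

    def to_json(self, path=None) -> str:
        def clean(v):
            return None if isinstance(v, float) and np.isnan(v) else v
        text = json.dumps({k: clean(v) for k, v in self.to_dict().items()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def table_row(self) -> dict:
        """Row with the customary table columns (foreground classes only)."""
        row = {"PA": self.pa, "MPA": self.mpa, "MIoU": self.miou}
        for n, v in zip(self.class_names, self.cpa_per_class):
            if n != "background":
                row[f"CPA({n.capitalize()})"] = v
        for n, v in zip(self.class_names, self.iou_per_class):
            if n != "background":
                row[f"IoU({n.capitalize()})"] = v
        return row


def compute_report(cm: ConfusionMatrix, cpa_mode: str = "precision") -> MetricsReport:
    """Score an accumulated confusion matrix into a MetricsReport."""
    cpas = [class_pixel_accuracy(cm, c, cpa_mode) for c in range(cm.num_classes)]
    ious = [iou(cm, c) for c in range(cm.num_classes)]
    undefined = [n for n, a, b in zip(cm.class_names, cpas, ious)
                 if np.isnan(a) or np.isnan(b)]
    return MetricsReport(
        pa=pixel_accuracy(cm),
        mpa=_defined_mean(cpas, "MPA"),
        miou=_defined_mean(ious, "MIoU"),
        cpa_per_class=cpas, iou_per_class=ious,
        class_names=list(cm.class_names), cpa_mode=cpa_mode,
        undefined_classes=undefined)
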