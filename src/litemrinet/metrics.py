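"""Confusion-matrix segmentation metrics.

Tumor is the positive class.  ``mIoU`` follows the two-class convention
in which tumor and background are each scored as foreground and the two
IoU values are averaged:

    mIoU = 1/2 * [ TP/(TP+FN+FP) + TN/(TN+FP+FN) ]

Dataset-level metrics are computed from globally accumulated pixel
counts by default (the per-image-mean alternative is available through
the evaluation driver).  Degenerate ratios (zero denominator) are
defined as 0 and flagged rather than raising, so all-background images
do not abort an evaluation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts", "accumulate",
           "compute_metrics", "format_report"]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies with tumor (label 1) as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """Fractional metrics in [0, 1]; ``degenerate`` lists metrics whose
    denominator was zero (reported as 0)."""

    miou: float
    f1: float
    oa: float
    precision: float
    recall: float
    degenerate: tuple[str, ...] = ()

    def as_percentages(self) -> dict[str, float]:
        return {k: 100.0 * getattr(self, k) for k in ("miou", "f1", "oa",
                                                      "precision", "recall")}


def _validate_mask(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0,1}}, found values {vals[:5]}")
    return mask.astype(bool)


def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Per-pixel tally of TP/FP/TN/FN for a predicted vs. reference mask."""
    pred = _validate_mask(pred_mask, "pred_mask")
    true = _validate_mask(true_mask, "true_mask")
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & true)),
        fp=int(np.count_nonzero(pred & ~true)),
        tn=int(np.count_nonzero(~pred & ~true)),
        fn=int(np.count_nonzero(~pred & true)),
    )


def accumulate(parts: Iterable[ConfusionCounts]) -> ConfusionCounts:
    """Component-wise sum; the identity is the all-zero count."""
    total = ConfusionCounts()
    for c in parts:
        total = total + c
    return total


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Precision, recall, F1, overall accuracy and two-class mIoU."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")
    degenerate: list[str] = []
    precision = _ratio(c.tp, c.tp + c.fp, "precision", degenerate)
    recall = _ratio(c.tp, c.tp + c.fn, "recall", degenerate)
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        degenerate.append("f1")
        f1 = 0.0
    oa = (c.tp + c.tn) / c.total
    iou_tumor = _ratio(c.tp, c.tp + c.fn + c.fp, "iou_tumor", degenerate)
    iou_background = _ratio(c.tn, c.tn + c.fp + c.fn, "iou_background", degenerate)
    miou = 0.5 * (iou_tumor + iou_background)
    return MetricReport(miou=miou, f1=f1, oa=oa, precision=precision,
                        recall=recall, degenerate=tuple(degenerate))


def format_report(reports: dict[str, MetricReport]) -> str:
    """Tabulate mIoU/F1/OA percentages to two decimals, one row per method."""
    header = f"{'Methods':<28}{'mIoU (%)':>10}{'F1-Score (%)':>14}{'OA (%)':>8}"
    lines = [header]
    for name, r in reports.items():
        p = r.as_percentages()
        lines.append(f"{name:<28}{p['miou']:>10.2f}{p['f1']:>14.2f}{p['oa']:>8.2f}")
    return "\n".join(lines)
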