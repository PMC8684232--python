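"""Pixel-wise segmentation evaluation: confusion counts and the five standard ratios.

Accuracy, sensitivity (true positive rate), specificity, Dice coefficient and
intersection-over-union (Jaccard index) are all derived from the per-pixel
confusion counts of a predicted mask against ground truth.  A ratio whose
denominator is zero is *undefined* and reported as NaN — never silently 0 —
so that dataset means are not corrupted by degenerate samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np

from .geometry import as_binary_mask

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """acc/sen/spe/dic/iou as fractions in [0, 1]; NaN marks an undefined ratio."""

    acc: float
    sen: float
    spe: float
    dic: float
    iou: float

    def as_dict(self) -> dict:
        return {"acc": self.acc, "sen": self.sen, "spe": self.spe, "dic": self.dic, "iou": self.iou}


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN pixels of ``pred`` against ``gt`` (same shape)."""
    p = as_binary_mask(pred).astype(bool)
    g = as_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the five ratios from confusion counts.

    ``dic = 2*TP / (2*TP + FN + FP)`` and ``iou = TP / (TP + FP + FN)`` satisfy
    the identity ``dic = 2*iou / (1 + iou)`` whenever both are defined.
    """
    if c.total <= 0:
        raise ValueError("confusion counts are all zero")
    return MetricsReport(
        acc=_ratio(c.tp + c.tn, c.total),
        sen=_ratio(c.tp, c.tp + c.fn),
        spe=_ratio(c.tn, c.tn + c.fp),
        dic=_ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
    )


def mask_iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Convenience: IoU of two masks (NaN when both are empty)."""
    return compute_metrics(confusion_counts(pred, gt)).iou
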