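"""Pixel-level evaluation: confusion counts, the four segmentation scores,
and a pooled-pixel ROC curve with trapezoidal AUC.

Scores follow the standard closed forms

    Pre  = TP / (TP + FP)
    Acc  = (TP + TN) / (TP + TN + FP + FN)
    Dice = 2 TP / (2 TP + FP + FN)
    MIoU = [TP/(TP+FP+FN) + TN/(TN+FP+FN)] / 2

with the zero-denominator convention that a vacuously perfect outcome
scores 1 (e.g. no predicted positives and no missed positives) and any
other undefined case scores 0.  Counts from multiple images may be summed
before scoring ("global" aggregation, the default in the evaluation loop).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion_counts(p, g, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; a pixel is predicted positive iff p >= threshold."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(g)
    if p.shape != g.shape:
        raise InvalidInputError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie strictly inside (0, 1)")
    if not np.isin(g, (0, 1)).all():
        raise InvalidInputError("ground-truth mask must be strictly binary")
    gb = g.astype(bool)
    pred = p >= threshold
    tp = int(np.count_nonzero(pred & gb))
    fp = int(np.count_nonzero(pred & ~gb))
    fn = int(np.count_nonzero(~pred & gb))
    tn = int(np.count_nonzero(~pred & ~gb))
    return ConfusionCounts(tp, tn, fp, fn)


def _safe_ratio(num: int, den: int, vacuous_perfect: bool) -> float:
    if den == 0:
        return 1.0 if vacuous_perfect else 0.0
    return num / den


@dataclass(frozen=True)
class MetricReport:
    precision: float
    accuracy: float
    dice: float
    miou: float
    auc: float | None = None
    counts: ConfusionCounts | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "accuracy": self.accuracy,
             "dice": self.dice, "miou": self.miou}
        if self.auc is not None:
            d["auc"] = self.auc
        if self.counts is not None:
            d.update(tp=self.counts.tp, tn=self.counts.tn,
                     fp=self.counts.fp, fn=self.counts.fn)
        return d


def segmentation_metrics(c: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Evaluate the four scores from pixel tallies (total must be positive)."""
    if c.total == 0:
        raise InvalidInputError("cannot compute metrics on zero pixels")
    precision = _safe_ratio(c.tp, c.tp + c.fp, vacuous_perfect=c.fn == 0)
    accuracy = (c.tp + c.tn) / c.total
    dice = _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, vacuous_perfect=True)
    iou_fg = _safe_ratio(c.tp, c.tp + c.fp + c.fn, vacuous_perfect=True)
    iou_bg = _safe_ratio(c.tn, c.tn + c.fp + c.fn, vacuous_perfect=True)
    return MetricReport(precision, accuracy, dice, (iou_fg + iou_bg) / 2.0, auc, c)


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points; first record is the all-negative point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "fpr", "tpr"])
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
                writer.writerow([repr(float(t)), repr(float(f)), repr(float(s))])
        return path


def roc_auc(p, g) -> tuple[RocCurve, float]:
    """ROC over pooled pixel probabilities and trapezoidal AUC.

    ``p`` and ``g`` may be single maps or sequences of maps; all pixels are
    pooled before thresholding.  Raises :class:`UndefinedMetricError` when
    the pooled ground truth contains a single class.
    """
    if isinstance(p, (list, tuple)):
        p = np.concatenate([np.asarray(a, dtype=float).ravel() for a in p])
        g = np.concatenate([np.asarray(a).ravel() for a in g])
    else:
        p = np.asarray(p, dtype=float).ravel()
        g = np.asarray(g).ravel()
    if p.shape != g.shape:
        raise InvalidInputError("pooled prediction and mask sizes differ")
    if not np.isin(g, (0, 1)).all():
        raise InvalidInputError("ground-truth mask must be strictly binary")
    g = g.astype(bool)
    n_pos = int(g.sum())
    n_neg = g.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: ground truth has a single class")

    order = np.argsort(-p, kind="stable")
    ps = p[order]
    gs = g[order]
    tp_cum = np.cumsum(gs)
    fp_cum = np.cumsum(~gs)
    # keep one operating point per distinct threshold (last index of each run)
    distinct = np.flatnonzero(np.diff(ps, append=-np.inf))
    thresholds = np.concatenate(([np.inf], ps[distinct]))
    tpr = np.concatenate(([0.0], tp_cum[distinct] / n_pos))
    fpr = np.concatenate(([0.0], fp_cum[distinct] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr), auc
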