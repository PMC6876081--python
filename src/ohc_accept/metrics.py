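"""Confusion-based evaluation metrics and ROC AUC.

Recall = TP/(TP+FN), Precision = TP/(TP+FP),
Accuracy = (TP+TN)/(TP+TN+FP+FN), F1 = 2*R*P/(R+P).
AUC is the area under the ROC curve computed by the Mann-Whitney rank
formulation, with ties contributing 1/2; this equals trapezoidal
integration of the ROC curve over all thresholds.  The ROC axes follow
the standard convention: TP rate = TP/(TP+FN) vertical, FP rate =
FP/(FP+TN) horizontal.

Zero-denominator metrics are defined as 0 with a warning, which keeps
degenerate folds (e.g. no predicted positives) reportable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "basic_metrics", "auc", "evaluate", "roc_points"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """The five headline metrics plus the confusion counts behind them."""

    recall: float
    precision: float
    accuracy: float
    f1: float
    auc: float
    counts: ConfusionCounts = field(default_factory=ConfusionCounts)
    threshold: float = 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion counts; predict positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0:
        raise ValueError("cannot compute confusion counts on empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels are misaligned")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; defining it as 0", name)
        return 0.0
    return num / den


def basic_metrics(counts: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Recall/precision/accuracy/F1 from confusion counts (AUC left at nan)."""
    if counts.total == 0:
        raise ValueError("confusion counts are empty")
    recall = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    precision = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    accuracy = counts.total and (counts.tp + counts.tn) / counts.total
    f1 = _safe_div(2 * recall * precision, recall + precision, "f1")
    return MetricsReport(
        recall=recall,
        precision=precision,
        accuracy=float(accuracy),
        f1=f1,
        auc=float("nan"),
        counts=counts,
        threshold=threshold,
    )


def auc(scores, labels) -> float:
    """ROC AUC via midranks: (sum of positive ranks - n+(n+ + 1)/2) / (n+ n-)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(scores, method="average")
    rank_sum = float(np.sum(ranks[labels == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def evaluate(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full report: thresholded confusion metrics plus AUC."""
    counts = confusion(scores, labels, threshold)
    report = basic_metrics(counts, threshold)
    report.auc = auc(scores, labels)
    return report


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as an array of (fp_rate, tp_rate) rows over all thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = max(int(np.sum(y == 1)), 1)
    n_neg = max(int(np.sum(y == 0)), 1)
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # collapse tied thresholds to their last point
    distinct = np.r_[np.diff(s) != 0, True]
    pts = np.column_stack([fp[distinct] / n_neg, tp[distinct] / n_pos])
    return np.vstack([[0.0, 0.0], pts])
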