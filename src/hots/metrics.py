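"""Binary-classification quality metrics: accuracy, F1, ROC AUC."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._utils import as_labels

__all__ = ["ConfusionCounts", "accuracy", "f1", "roc_auc"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of a binary classifier."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = as_labels(y_true)
        y_pred = as_labels(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred lengths differ")
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def accuracy(c: ConfusionCounts) -> float:
    """Proportion of correct predictions, (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero predictions")
    return (c.TP + c.TN) / c.total


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0."""
    if c.TP + c.FP + c.FN == 0:
        log.warning("F1 undefined (no positive labels or predictions); returning 0")
        return 0.0
    return 2.0 * c.TP / (2.0 * c.TP + c.FP + c.FN)


def roc_auc(scores, y) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Midranks handle tied scores, so constant scores give 0.5 exactly.
    """
    y = as_labels(y)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != y.shape:
        raise ValueError("scores and labels lengths differ")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes present")
    ranks = rankdata(scores)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
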