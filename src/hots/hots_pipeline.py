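"""Hollow-tree Super: cross-validated, signed, per-class feature importance.

The pipeline turns per-prediction path decompositions of a boosted-tree
classifier into global per-class feature-importance scores:

1. decompose every held-out prediction into per-feature log-odds
   contributions, oriented to the predicted class;
2. separate the decompositions of positive- and negative-class predictions;
3. drop incorrect predictions and those with confidence below a threshold
   (default 70%);
4. within each class, average each feature's contribution over the retained
   predictions;
5. attach a direction: multiply the positive-class averages by the sign of
   (class-1 mean - class-0 mean) of each feature, and the negative-class
   averages by the opposite sign;
6. repeat over k stratified cross-validation folds (default 5), averaging
   the signed weights across folds and counting, per feature, the folds in
   which it carried any weight.

Magnitudes are comparable across features because every step is an average
of additive log-odds terms; the sign step supplies the direction the raw
oriented magnitudes lack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_labels, as_matrix
from . import metrics as _metrics
from .decomposition import Decomposition, decompose_ensemble, orient_to_predicted_class
from .tree_core import TrainConfig, train_boosted

__all__ = [
    "HOTSConfig",
    "ClassImportance",
    "HOTSResult",
    "filter_predictions",
    "split_by_class",
    "aggregate_weights",
    "infer_signs",
    "stratified_folds",
    "run_hots",
    "fold_counts",
]

log = logging.getLogger(__name__)


@dataclass
class HOTSConfig:
    """Pipeline parameters.

    prob_threshold
        Minimum confidence (probability of the predicted class) a correct
        prediction needs to be retained; predictions *below* the threshold
        are dropped, equality is kept.
    k_folds, stratified, seed
        Cross-validation layout.  Folds are stratified by default and the
        seeded shuffle makes the run reproducible.
    appearance_epsilon
        A feature "appears" in a fold when the larger of its two class
        weight magnitudes exceeds this.
    fold_average
        "all" (default) averages signed weights over all k folds, counting
        absent folds as 0, which keeps magnitudes comparable across
        features; "present" averages only over folds where the feature
        appears.
    """

    prob_threshold: float = 0.7
    k_folds: int = 5
    stratified: bool = True
    seed: int = 0
    appearance_epsilon: float = 1e-12
    fold_average: str = "all"
    train_cfg: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.appearance_epsilon < 0:
            raise ValueError("appearance_epsilon must be >= 0")
        if self.fold_average not in ("all", "present"):
            raise ValueError("fold_average must be 'all' or 'present'")


@dataclass
class ClassImportance:
    """Signed per-feature average weights for one fold."""

    positive_weights: np.ndarray
    negative_weights: np.ndarray
    n_retained_pos: int
    n_retained_neg: int
    fold_index: int


@dataclass
class HOTSResult:
    """Cross-validated HOTS output."""

    feature_names: list[str]
    per_fold: list[ClassImportance]
    mean_positive: np.ndarray
    mean_negative: np.ndarray
    fold_counts: np.ndarray
    per_fold_accuracy: list[float]
    mean_accuracy: float
    per_fold_metrics: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per feature, per-fold and mean columns."""
        data = {
            "feature": self.feature_names,
            "mean_pos": self.mean_positive,
            "mean_neg": self.mean_negative,
            "fold_count": self.fold_counts,
        }
        for ci in self.per_fold:
            data[f"pos_fold{ci.fold_index + 1}"] = ci.positive_weights
            data[f"neg_fold{ci.fold_index + 1}"] = ci.negative_weights
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------


def filter_predictions(
    decomps: list[Decomposition], threshold: float = 0.7
) -> list[Decomposition]:
    """Keep correct predictions made with confidence >= threshold.

    Confidence is the probability of the *predicted* class, max(p, 1-p).
    Predictions strictly below the threshold are filtered out, so a
    confidence exactly at the threshold survives.
    """
    for d in decomps:
        if d.true_class is None:
            raise ValueError(
                f"decomposition {d.sample_id!r} lacks true_class; filtering "
                "requires labelled predictions"
            )
    return [
        d
        for d in decomps
        if d.predicted_class == d.true_class and d.confidence >= threshold
    ]


def split_by_class(
    decomps: list[Decomposition],
) -> dict[str, list[Decomposition]]:
    """Partition by predicted class, orienting each to its predicted class.

    After filtering, predicted class equals true class, so the partition is
    also a partition by label.
    """
    oriented = [orient_to_predicted_class(d) for d in decomps]
    return {
        "positive": [d for d in oriented if d.predicted_class == 1],
        "negative": [d for d in oriented if d.predicted_class == 0],
    }


def aggregate_weights(
    decomps: list[Decomposition], feature_names: list[str] | None = None
) -> np.ndarray:
    """Average per-feature contributions over a set of decompositions.

    The normaliser is the number of retained predictions in this set (the
    class partition after filtering), giving an average weight per
    prediction.  An empty set yields all-zero weights with a warning; this
    needs ``feature_names`` to size the output.
    """
    if not decomps:
        if feature_names is None:
            raise ValueError("empty decomposition set and no feature_names given")
        log.warning("no retained predictions in partition; weights set to zero")
        return np.zeros(len(feature_names), dtype=np.float64)
    names = decomps[0].feature_names
    for d in decomps:
        if d.feature_names != names:
            raise ValueError("decompositions disagree on feature names")
    stacked = np.stack([d.contributions for d in decomps])
    return stacked.sum(axis=0) / len(decomps)


def infer_signs(
    pos_w: np.ndarray, neg_w: np.ndarray, X, y
) -> tuple[np.ndarray, np.ndarray]:
    """Attach direction from class-conditional feature means.

    For each feature, s = sign(mean(X | y=1) - mean(X | y=0)).  The
    positive-class weights are multiplied by s, the negative-class weights
    by -s.  Features whose class means are exactly equal get sign 0: both
    weights are zeroed and a warning is logged rather than guessing a
    direction.
    """
    X, names = as_matrix(X)
    y = as_labels(y)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("cannot compute class means: a class is absent in y")
    s = np.sign(X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0))
    if (s == 0).any():
        zeroed = [names[i] for i in np.nonzero(s == 0)[0]]
        log.warning(
            "equal class means for %s; their signed weights are set to 0", zeroed
        )
    return pos_w * s, neg_w * (-s)


def stratified_folds(y: np.ndarray, k: int, seed: int, stratified: bool = True):
    """Seeded k-fold test-index partition, stratified by label.

    Indices are shuffled once, then assigned round-robin within each class,
    so every sample lands in exactly one test fold and the partition is
    invariant under complementing the labels (the two class groups swap
    names but keep their members and their round-robin order).
    """
    y = as_labels(y)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    if stratified:
        groups = [perm[y[perm] == c] for c in (0, 1)]
    else:
        groups = [perm]
    for members in groups:
        fold_of[members] = np.arange(members.size) % k
    return [np.sort(np.nonzero(fold_of == f)[0]) for f in range(k)]


def run_hots(X, y, cfg: HOTSConfig | None = None) -> HOTSResult:
    """Run the full cross-validated pipeline.

    Per fold: fit a boosted ensemble on the training split, decompose every
    test-split prediction, filter, separate by class, aggregate, and sign
    using the test split's class means (keeping the direction estimate
    out-of-sample).  Cross-fold means and per-feature fold counts are
    computed over all k folds.
    """
    cfg = cfg or HOTSConfig()
    X, names = as_matrix(X)
    y = as_labels(y, require_both_classes=True)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if cfg.stratified and min(n_pos, n_neg) < cfg.k_folds:
        raise ValueError(
            f"need at least k_folds={cfg.k_folds} samples per class for "
            f"stratified folds, got {n_pos} positive / {n_neg} negative"
        )

    per_fold: list[ClassImportance] = []
    per_fold_accuracy: list[float] = []
    per_fold_metrics: list[dict] = []

    folds = stratified_folds(y, cfg.k_folds, cfg.seed, cfg.stratified)
    for fold_index, test_idx in enumerate(folds):
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        ens = train_boosted(
            pd.DataFrame(X[train_mask], columns=names), y[train_mask], cfg.train_cfg
        )

        decomps = [
            decompose_ensemble(ens, X[i], true_class=y[i], sample_id=int(i))
            for i in test_idx
        ]
        y_test = y[test_idx]
        y_pred = np.array([dd.predicted_class for dd in decomps], dtype=np.int8)
        counts = _metrics.ConfusionCounts.from_predictions(y_test, y_pred)
        acc = _metrics.accuracy(counts)
        fold_metric = {"accuracy": acc, "f1": _metrics.f1(counts)}
        try:
            fold_metric["roc_auc"] = _metrics.roc_auc(
                np.array([dd.probability for dd in decomps]), y_test
            )
        except ValueError:
            fold_metric["roc_auc"] = float("nan")
        per_fold_accuracy.append(acc)
        per_fold_metrics.append(fold_metric)

        kept = filter_predictions(decomps, cfg.prob_threshold)
        parts = split_by_class(kept)
        pos_w = aggregate_weights(parts["positive"], names)
        neg_w = aggregate_weights(parts["negative"], names)
        pos_w, neg_w = infer_signs(pos_w, neg_w, X[test_idx], y_test)
        per_fold.append(
            ClassImportance(
                positive_weights=pos_w,
                negative_weights=neg_w,
                n_retained_pos=len(parts["positive"]),
                n_retained_neg=len(parts["negative"]),
                fold_index=fold_index,
            )
        )

    pos_stack = np.stack([ci.positive_weights for ci in per_fold])
    neg_stack = np.stack([ci.negative_weights for ci in per_fold])
    presence = (
        np.maximum(np.abs(pos_stack), np.abs(neg_stack)) > cfg.appearance_epsilon
    )
    counts_per_feature = presence.sum(axis=0).astype(np.int64)
    if cfg.fold_average == "all":
        mean_pos = pos_stack.mean(axis=0)
        mean_neg = neg_stack.mean(axis=0)
    else:
        denom = np.maximum(counts_per_feature, 1).astype(np.float64)
        mean_pos = np.where(
            counts_per_feature > 0, pos_stack.sum(axis=0) / denom, 0.0
        )
        mean_neg = np.where(
            counts_per_feature > 0, neg_stack.sum(axis=0) / denom, 0.0
        )

    return HOTSResult(
        feature_names=names,
        per_fold=per_fold,
        mean_positive=mean_pos,
        mean_negative=mean_neg,
        fold_counts=counts_per_feature,
        per_fold_accuracy=per_fold_accuracy,
        mean_accuracy=float(np.mean(per_fold_accuracy)),
        per_fold_metrics=per_fold_metrics,
    )


def fold_counts(
    result: HOTSResult, appearance_epsilon: float = 1e-12
) -> np.ndarray:
    """Recount, per feature, the folds where it carries nonzero weight.

    A feature counts in a fold when the larger of its positive/negative
    signed weight magnitudes exceeds ``appearance_epsilon``.
    """
    pos = np.stack([ci.positive_weights for ci in result.per_fold])
    neg = np.stack([ci.negative_weights for ci in result.per_fold])
    return (
        (np.maximum(np.abs(pos), np.abs(neg)) > appearance_epsilon)
        .sum(axis=0)
        .astype(np.int64)
    )
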