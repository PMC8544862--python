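"""Classical tree feature-importance baselines.

Three comparison methods: impurity-decrease (Gini) importance, permutation
importance, and one/two-feature partial dependence.  All operate on the
package's own tree/ensemble objects, so they apply equally to trained and
imported models.  Gini importance is magnitude-only; permutation importance
is magnitude-only; partial dependence shows direction but for at most two
features at a time — exactly the gaps the decomposition pipeline fills.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import as_labels, as_matrix, sigmoid
from .tree_core import BoostedEnsemble, TreeModel

__all__ = [
    "PDPResult",
    "PermutationImportance",
    "gini_importance",
    "permutation_importance",
    "pdp",
]


@dataclass
class PDPResult:
    """Partial-dependence grid(s) and averaged predictions.

    ``values`` is a vector for one feature, a ``len(grid_1) x len(grid_2)``
    matrix for two.
    """

    grid_1: np.ndarray
    values: np.ndarray
    feature_names: list[str]
    grid_2: np.ndarray | None = None


@dataclass
class PermutationImportance:
    """Mean and sd of the score drop per feature over repeated shuffles."""

    importances_mean: np.ndarray
    importances_sd: np.ndarray
    feature_names: list[str]
    baseline_score: float
    metric: str


def _model_trees(model: TreeModel | BoostedEnsemble) -> list[TreeModel]:
    return model.trees if isinstance(model, BoostedEnsemble) else [model]


def _predict_proba(model: TreeModel | BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    if isinstance(model, BoostedEnsemble):
        return model.predict_proba(X)
    values = model.predict_values(X)
    return sigmoid(values) if model.value_space == "margin" else values


def gini_importance(model: TreeModel | BoostedEnsemble) -> np.ndarray:
    """Normalised total impurity decrease credited to each feature.

    Each split on feature f contributes ``n_parent * imp_parent -
    n_left * imp_left - n_right * imp_right``; contributions are summed
    across trees for ensembles and normalised to sum to 1.  Requires nodes
    to carry cover and impurity statistics (models trained here always do;
    imported dumps may not).
    """
    trees = _model_trees(model)
    importance = np.zeros(model.n_features, dtype=np.float64)
    for tree in trees:
        for node in tree.nodes.values():
            if node.is_leaf:
                continue
            left, right = tree.nodes[node.left], tree.nodes[node.right]
            for nd in (node, left, right):
                if nd.impurity is None or nd.n_samples <= 0:
                    raise ValueError(
                        "node statistics missing; retrain with statistics "
                        "(cover and impurity) to compute Gini importance"
                    )
            importance[node.feature_index] += (
                node.n_samples * node.impurity
                - left.n_samples * left.impurity
                - right.n_samples * right.impurity
            )
    total = importance.sum()
    return importance / total if total > 0 else importance


def permutation_importance(
    model: TreeModel | BoostedEnsemble,
    X,
    y,
    n_repeats: int = 10,
    seed: int | None = 0,
    metric: str = "accuracy",
) -> PermutationImportance:
    """Score drop when one feature's column is shuffled, others kept intact.

    The drop is baseline score minus the mean score over ``n_repeats``
    seeded shuffles of that column only (for log-loss, which decreases with
    quality, the drop is the mean permuted loss minus the baseline loss so
    that larger remains worse).  A feature no split ever uses leaves the
    predictions untouched, hence a drop of exactly zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if metric not in ("accuracy", "log_loss"):
        raise ValueError("metric must be 'accuracy' or 'log_loss'")
    X, names = as_matrix(X, getattr(model, "feature_names", None))
    y = as_labels(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")

    def score(mat: np.ndarray) -> float:
        p = _predict_proba(model, mat)
        if metric == "accuracy":
            return float(((p >= 0.5).astype(np.int8) == y).mean())
        eps = 1e-12
        p = np.clip(p, eps, 1 - eps)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    baseline = score(X)
    rng = np.random.default_rng(seed)
    mean = np.empty(X.shape[1])
    sd = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            s = score(Xp)
            drops[r] = baseline - s if metric == "accuracy" else s - baseline
        mean[j] = drops.mean()
        sd[j] = drops.std()
    return PermutationImportance(
        importances_mean=mean,
        importances_sd=sd,
        feature_names=names,
        baseline_score=baseline,
        metric=metric,
    )


def pdp(
    model: TreeModel | BoostedEnsemble,
    X,
    features,
    grid_resolution: int = 50,
) -> PDPResult:
    """Partial dependence of the model output on one or two features.

    The grid for a feature is its unique sorted observed values when there
    are at most ``grid_resolution`` of them, otherwise ``grid_resolution``
    equispaced quantiles.  The value at a grid point is the mean model
    prediction over all rows with the swept feature(s) overwritten by the
    grid point.  Probability-space outputs stay within [0, 1].
    """
    features = [int(f) for f in np.atleast_1d(features)]
    if not 1 <= len(features) <= 2:
        raise ValueError(
            "partial dependence is limited to one or two features at a time"
        )
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    X, names = as_matrix(X, getattr(model, "feature_names", None))

    def grid_for(j: int) -> np.ndarray:
        uniq = np.unique(X[:, j])
        if uniq.size <= grid_resolution:
            return uniq
        return np.unique(np.quantile(uniq, np.linspace(0, 1, grid_resolution)))

    g1 = grid_for(features[0])
    if len(features) == 1:
        values = np.empty(g1.size)
        for i, v in enumerate(g1):
            Xi = X.copy()
            Xi[:, features[0]] = v
            values[i] = _predict_proba(model, Xi).mean()
        return PDPResult(
            grid_1=g1, values=values, feature_names=[names[features[0]]]
        )
    g2 = grid_for(features[1])
    values = np.empty((g1.size, g2.size))
    for i, v1 in enumerate(g1):
        for j, v2 in enumerate(g2):
            Xi = X.copy()
            Xi[:, features[0]] = v1
            Xi[:, features[1]] = v2
            values[i, j] = _predict_proba(model, Xi).mean()
    return PDPResult(
        grid_1=g1,
        grid_2=g2,
        values=values,
        feature_names=[names[features[0]], names[features[1]]],
    )
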