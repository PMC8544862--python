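"""Additive per-prediction feature attribution along decision paths.

A prediction made by a decision tree can be rewritten as the value at the
root (the *bias*, the top-level sample average) plus, for every split taken
on the way down, the change in node expected value attributed to the split
feature:

    f(x) = bias + sum_k contribution(x, k)

with ``k`` running over features.  The identity is exact (telescoping sum of
child-minus-parent increments).  For a single probability-space tree the
terms are probabilities; for a boosted ensemble the same walk is performed
in every tree in margin space and the per-feature increments add, so the
terms are log-odds contributions and the bias is the base score plus the sum
of per-tree root expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._utils import sigmoid
from .tree_core import MARGIN, PROBABILITY, BoostedEnsemble, TreeModel

__all__ = [
    "PathStep",
    "Decomposition",
    "trace_path",
    "decompose_tree",
    "decompose_ensemble",
    "orient_to_predicted_class",
]

PROB_SPACE = "probability"
LOG_ODDS_SPACE = "log_odds"


@dataclass(frozen=True)
class PathStep:
    """One split taken on a root-to-leaf walk.

    ``delta`` is the expected-value increment: value of the child taken
    minus value of the parent.
    """

    node_id: int
    feature_index: int
    delta: float


@dataclass
class Decomposition:
    """One prediction expressed as bias plus per-feature contributions.

    ``bias + contributions.sum()`` equals the raw model output: the leaf
    probability for a single tree, the total margin for an ensemble.
    """

    bias: float
    contributions: np.ndarray
    feature_names: list[str]
    space: str  # "probability" | "log_odds"
    probability: float
    predicted_class: int
    true_class: int | None = None
    sample_id: int | str | None = None

    @property
    def output(self) -> float:
        """Raw model output reconstructed from the decomposition."""
        return self.bias + float(self.contributions.sum())

    @property
    def confidence(self) -> float:
        """Probability assigned to the predicted class: max(p, 1 - p)."""
        return max(self.probability, 1.0 - self.probability)

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "bias": self.bias,
            "probability": self.probability,
            "predicted_class": self.predicted_class,
            "space": self.space,
            "contributions": {
                name: float(v)
                for name, v in zip(self.feature_names, self.contributions)
            },
        }


def trace_path(tree: TreeModel, x) -> list[PathStep]:
    """Walk the root-to-leaf path of ``x`` and record per-split increments.

    One step per internal node visited; the step deltas telescope to
    ``leaf value - root value``.  A single-leaf tree yields no steps.
    """
    path = tree.decision_path(x)
    steps = []
    for parent_id, child_id in zip(path[:-1], path[1:]):
        parent = tree.nodes[parent_id]
        child = tree.nodes[child_id]
        steps.append(
            PathStep(
                node_id=parent_id,
                feature_index=parent.feature_index,
                delta=child.value - parent.value,
            )
        )
    return steps


def _accumulate(tree: TreeModel, x, out: np.ndarray) -> float:
    """Add path increments per feature into ``out``; return leaf value."""
    for step in trace_path(tree, x):
        out[step.feature_index] += step.delta
    return tree.nodes[tree.decision_path(x)[-1]].value


def decompose_tree(
    tree: TreeModel, x, true_class: int | None = None, sample_id=None
) -> Decomposition:
    """Decompose a single-tree prediction.

    Contributions of a feature sum the increments of every split on that
    feature along the path (a feature may be split repeatedly); the bias is
    the root value.
    """
    contributions = np.zeros(tree.n_features, dtype=np.float64)
    leaf_value = _accumulate(tree, x, contributions)
    bias = tree.nodes[tree.root_id].value
    if tree.value_space == PROBABILITY:
        space, probability = PROB_SPACE, float(leaf_value)
    else:
        space, probability = LOG_ODDS_SPACE, float(sigmoid(leaf_value))
    return Decomposition(
        bias=float(bias),
        contributions=contributions,
        feature_names=list(tree.feature_names),
        space=space,
        probability=probability,
        predicted_class=int(probability >= 0.5),
        true_class=None if true_class is None else int(true_class),
        sample_id=sample_id,
    )


def decompose_ensemble(
    ens: BoostedEnsemble, x, true_class: int | None = None, sample_id=None
) -> Decomposition:
    """Decompose a boosted-ensemble prediction in log-odds space.

    Per-feature contributions are summed over all trees' path increments;
    the bias collects the base score plus every tree's root expectation.
    Exact additivity over trees holds by construction.
    """
    contributions = np.zeros(ens.n_features, dtype=np.float64)
    bias = ens.base_score
    total_margin = ens.base_score
    for tree in ens.trees:
        leaf_value = _accumulate(tree, x, contributions)
        bias += tree.nodes[tree.root_id].value
        total_margin += leaf_value
    probability = float(sigmoid(total_margin))
    return Decomposition(
        bias=float(bias),
        contributions=contributions,
        feature_names=list(ens.feature_names),
        space=LOG_ODDS_SPACE,
        probability=probability,
        predicted_class=int(probability >= 0.5),
        true_class=None if true_class is None else int(true_class),
        sample_id=sample_id,
    )


def orient_to_predicted_class(d: Decomposition) -> Decomposition:
    """Express log-odds contributions relative to the predicted class.

    For class-1 predictions the contributions already are the log odds of
    the predicted class; for class-0 predictions they are negated (log odds
    of class 0 = -log odds of class 1).  Applying the map twice to a class-0
    decomposition returns the original values: the map is a stateless
    negation keyed on ``predicted_class``, not an idempotent flag.
    """
    if d.space != LOG_ODDS_SPACE:
        raise ValueError("orientation defined for log-odds only")
    if d.predicted_class == 1:
        return d
    return replace(d, contributions=-d.contributions)
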