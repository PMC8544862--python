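"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own path-walking code:
they enumerate tree structure recursively and re-derive expected values
from first principles, so agreement with the implementation is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import hots
from hots.tree_core import TreeModel


@pytest.fixture
def worked_example():
    tree, probe = hots.worked_example_tree()
    return tree, probe


@pytest.fixture
def small_data():
    """200 x 5 planted-signal table, feature f0 informative with +2 sd."""
    spec = hots.SyntheticSpec(
        n_samples=200, n_features=5, informative=[(0, 2.0)], seed=7
    )
    return hots.make_synthetic(spec)


@pytest.fixture
def small_tree(small_data):
    X, y = small_data
    return hots.train_cart(X, y, hots.TrainConfig(max_depth=3))


@pytest.fixture
def small_ensemble(small_data):
    X, y = small_data
    return hots.train_boosted(X, y, hots.TrainConfig(n_trees=8, max_depth=3))


def random_trained_tree(seed: int, max_depth: int = 4) -> TreeModel:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 120))
    d = int(rng.integers(2, 6))
    X = rng.normal(size=(n, d))
    y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return hots.train_cart(X, y, hots.TrainConfig(max_depth=max_depth))


def leaf_regions_with_contributions(tree: TreeModel):
    """Enumerate every leaf: a probe routed to it + brute-force attributions.

    Walks the tree recursively, tracking per-feature (lower, upper] bounds
    and summing child-minus-parent value increments per feature.  The probe
    is built from the bounds (upper bound when one exists, since routing is
    'x <= threshold goes left'; otherwise just above the lower bound).
    """
    results = []

    def rec(nid, bounds, contrib):
        node = tree.nodes[nid]
        if node.is_leaf:
            x = np.zeros(tree.n_features)
            for f, (lo, hi) in bounds.items():
                if hi is not None:
                    x[f] = hi
                elif lo is not None:
                    x[f] = lo + 1.0
            results.append((nid, x, dict(contrib)))
            return
        f, t = node.feature_index, node.threshold
        lo, hi = bounds.get(f, (None, None))
        for child_id, new_bounds in (
            (node.left, (lo, t if hi is None else min(hi, t))),
            (node.right, (t if lo is None else max(lo, t), hi)),
        ):
            child = tree.nodes[child_id]
            new_contrib = dict(contrib)
            new_contrib[f] = new_contrib.get(f, 0.0) + (child.value - node.value)
            rec(child_id, {**bounds, f: new_bounds}, new_contrib)

    rec(tree.root_id, {}, {})
    return results


def make_decomp(
    contributions,
    probability,
    predicted_class,
    true_class,
    space="log_odds",
    names=None,
    sample_id=None,
):
    """Hand-build a Decomposition for pipeline-step tests."""
    contributions = np.asarray(contributions, dtype=float)
    if names is None:
        names = [f"f{i}" for i in range(contributions.size)]
    return hots.Decomposition(
        bias=0.0,
        contributions=contributions,
        feature_names=list(names),
        space=space,
        probability=probability,
        predicted_class=predicted_class,
        true_class=true_class,
        sample_id=sample_id,
    )
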