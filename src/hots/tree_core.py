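"""Decision-tree and boosted-ensemble structures with deterministic trainers.

Two kinds of model are represented:

* probability-space single trees (CART, exact greedy Gini splits), where every
  node stores the class-1 fraction of the training rows routed through it;
* log-odds (margin) boosted ensembles (Newton gradient boosting with a
  logistic loss and an L2 leaf regulariser), where leaves store shrunken
  Newton weights and internal nodes store the cover-weighted mean of their
  descendant leaves.

Both keep an expected model output at *every* node because the path
decomposition downstream differences parent and child values along a
prediction path.  An importer/exporter for the common boosted-model JSON dump
dialect (``nodeid`` / ``split`` / ``split_condition`` / ``yes`` / ``no`` /
``leaf`` / ``cover``) allows externally trained boosters to be explained.

Routing convention everywhere: ``x[feature] <= threshold`` goes left.
Split thresholds are midpoints between consecutive distinct sorted values;
ties in split quality are broken toward the lowest feature index, then the
lowest threshold, so training is fully deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from ._utils import as_labels, as_matrix, sigmoid

__all__ = [
    "TreeNode",
    "TreeModel",
    "BoostedEnsemble",
    "TrainConfig",
    "Prediction",
    "train_cart",
    "train_boosted",
    "predict",
    "import_model_dump",
    "export_model_dump",
    "tree_to_json",
    "tree_from_json",
]

_GAIN_EPS = 1e-12

PROBABILITY = "probability"
MARGIN = "margin"


@dataclass
class TreeNode:
    """One node of a binary decision tree.

    ``value`` is the expected model output at the node: a class-1 probability
    for probability-space trees, a margin (log-odds increment) for boosted
    trees.  ``n_samples`` is the cover — the number of training samples routed
    through the node (a hessian sum, hence fractional, for imported boosters).
    Leaves have no split; internal nodes have both children and a
    ``(feature_index, threshold)`` pair.
    """

    node_id: int
    value: float
    n_samples: float = 0.0
    feature_index: int | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None
    impurity: float | None = None

    def __post_init__(self):
        split_bits = (
            self.feature_index is not None,
            self.threshold is not None,
            self.left is not None,
            self.right is not None,
        )
        if any(split_bits) and not all(split_bits):
            raise ValueError(
                f"node {self.node_id}: a node has either both children and a "
                "(feature_index, threshold) or neither"
            )
        if self.n_samples < 0:
            raise ValueError(f"node {self.node_id}: negative cover")

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None


@dataclass
class TreeModel:
    """A rooted binary tree over ``n_features`` numeric features."""

    nodes: dict[int, TreeNode]
    root_id: int
    n_features: int
    feature_names: list[str]
    value_space: str = PROBABILITY

    def __post_init__(self):
        if self.value_space not in (PROBABILITY, MARGIN):
            raise ValueError(f"unknown value_space {self.value_space!r}")
        self.validate()

    def validate(self) -> None:
        """Check rooted-binary-tree structure and field invariants."""
        if self.root_id not in self.nodes:
            raise ValueError("root_id not among nodes")
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length != n_features")
        seen: set[int] = set()
        parents: set[int] = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError(f"node {nid} reachable twice (cycle or DAG)")
            seen.add(nid)
            node = self.nodes[nid]
            if node.is_leaf:
                continue
            if not 0 <= node.feature_index < self.n_features:
                raise ValueError(
                    f"node {nid}: feature_index {node.feature_index} out of range"
                )
            for child in (node.left, node.right):
                if child not in self.nodes:
                    raise ValueError(f"node {nid}: missing child {child}")
                if child in parents or child == self.root_id:
                    raise ValueError(f"node {child} has more than one parent")
                parents.add(child)
                stack.append(child)
        if seen != set(self.nodes):
            raise ValueError("unreachable nodes present")
        if self.value_space == PROBABILITY:
            for node in self.nodes.values():
                if not 0.0 <= node.value <= 1.0:
                    raise ValueError(
                        f"node {node.node_id}: probability-space value "
                        f"{node.value} outside [0, 1]"
                    )

    # -- navigation ---------------------------------------------------------

    def decision_path(self, x) -> list[int]:
        """Node ids visited from root to leaf for one sample."""
        x = np.asarray(x, dtype=np.float64).ravel()
        if x.shape[0] != self.n_features:
            raise ValueError(
                f"sample has {x.shape[0]} values, model expects {self.n_features}"
            )
        path = []
        nid = self.root_id
        while True:
            path.append(nid)
            node = self.nodes[nid]
            if node.is_leaf:
                return path
            nid = node.left if x[node.feature_index] <= node.threshold else node.right

    def predict_value(self, x) -> float:
        return self.nodes[self.decision_path(x)[-1]].value

    def predict_values(self, X) -> np.ndarray:
        """Vectorised leaf-value lookup for a matrix of samples."""
        X, _ = as_matrix(X, self.feature_names)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"table has {X.shape[1]} columns, model expects {self.n_features}"
            )
        out = np.empty(X.shape[0], dtype=np.float64)
        stack = [(self.root_id, np.arange(X.shape[0]))]
        while stack:
            nid, idx = stack.pop()
            node = self.nodes[nid]
            if node.is_leaf:
                out[idx] = node.value
            elif idx.size:
                go_left = X[idx, node.feature_index] <= node.threshold
                stack.append((node.left, idx[go_left]))
                stack.append((node.right, idx[~go_left]))
        return out

    def leaves(self) -> Iterator[TreeNode]:
        return (n for n in self.nodes.values() if n.is_leaf)

    def depth(self) -> int:
        def rec(nid: int) -> int:
            node = self.nodes[nid]
            if node.is_leaf:
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root_id)


@dataclass
class BoostedEnsemble:
    """Ordered margin trees plus a global log-odds offset.

    Predicted probability is ``sigmoid(base_score + sum of tree margins)``.
    """

    trees: list[TreeModel]
    base_score: float
    n_features: int
    feature_names: list[str]

    def __post_init__(self):
        for t in self.trees:
            if t.value_space != MARGIN:
                raise ValueError("ensemble trees must be margin-space")
            if t.n_features != self.n_features or t.feature_names != self.feature_names:
                raise ValueError("ensemble trees disagree on features")

    def margin(self, X) -> np.ndarray:
        X, _ = as_matrix(X, self.feature_names)
        total = np.full(X.shape[0], self.base_score, dtype=np.float64)
        for tree in self.trees:
            total += tree.predict_values(X)
        return total

    def predict_proba(self, X) -> np.ndarray:
        return sigmoid(self.margin(X))


@dataclass
class TrainConfig:
    """Hyperparameters for the deterministic trainers.

    ``n_trees``, ``learning_rate`` and ``reg_lambda`` only affect boosting.
    ``seed`` is carried for interface uniformity; the exact greedy trainers
    are deterministic functions of the data.
    """

    max_depth: int = 6
    n_trees: int = 100
    learning_rate: float = 0.3
    min_samples_split: int = 2
    seed: int = 0
    reg_lambda: float = 1.0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")


@dataclass
class Prediction:
    probability: float
    margin: float | None
    predicted_class: int


def predict(model: TreeModel | BoostedEnsemble, x) -> Prediction:
    """Predict one sample with either model kind.

    Single probability trees report the leaf value as the class-1
    probability (margin is not defined for them); ensembles report the
    logistic of the accumulated margin.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != model.n_features:
        raise ValueError(
            f"sample has {x.shape[0]} values, model expects {model.n_features}"
        )
    if isinstance(model, BoostedEnsemble):
        m = float(model.margin(x.reshape(1, -1))[0])
        p = float(sigmoid(m))
        return Prediction(probability=p, margin=m, predicted_class=int(p >= 0.5))
    value = model.predict_value(x)
    if model.value_space == MARGIN:
        p = float(sigmoid(value))
        return Prediction(probability=p, margin=float(value), predicted_class=int(p >= 0.5))
    return Prediction(probability=float(value), margin=None, predicted_class=int(value >= 0.5))


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------


def _sorted_views(X: np.ndarray):
    """Per-feature stable sort of a node's rows; shared by both criteria."""
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    valid = xs[1:] > xs[:-1]  # boundary b splits rows 0..b | b+1..m-1
    return order, xs, valid


def _pick_candidate(quality: np.ndarray, xs: np.ndarray, maximize: bool):
    """Deterministic argbest with (feature_index, threshold) tie-breaking.

    ``quality`` is (m-1, d); invalid candidates must already be masked to
    -inf (maximize) or +inf (minimize).  Returns (feature, threshold, best)
    or None when no finite candidate exists.
    """
    best = quality.max() if maximize else quality.min()
    if not np.isfinite(best):
        return None
    rows, cols = np.nonzero(quality == best)
    thresholds = 0.5 * (xs[rows, cols] + xs[rows + 1, cols])
    # midpoint of adjacent floats may round up to the right value; pull it
    # back so "x <= threshold" keeps the intended left group
    hi = xs[rows + 1, cols]
    lo = xs[rows, cols]
    thresholds = np.where(thresholds >= hi, lo, thresholds)
    pick = np.lexsort((thresholds, cols))[0]
    return int(cols[pick]), float(thresholds[pick]), float(best)


def _gini(p1: float) -> float:
    return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)


def _best_split_gini(X: np.ndarray, y: np.ndarray):
    """Exact greedy Gini split: minimise child-weighted impurity."""
    m = X.shape[0]
    if m < 2:
        return None
    order, xs, valid = _sorted_views(X)
    ysort = y[order].astype(np.float64)
    c1 = np.cumsum(ysort, axis=0)
    n_left = np.arange(1, m, dtype=np.float64)[:, None]
    n_right = m - n_left
    c1_left = c1[:-1]
    c1_right = c1[-1] - c1_left
    p_left = c1_left / n_left
    p_right = c1_right / n_right
    gini_left = 1.0 - p_left**2 - (1.0 - p_left) ** 2
    gini_right = 1.0 - p_right**2 - (1.0 - p_right) ** 2
    weighted = (n_left * gini_left + n_right * gini_right) / m
    weighted = np.where(valid, weighted, np.inf)
    cand = _pick_candidate(weighted, xs, maximize=False)
    if cand is None:
        return None
    feature, threshold, best = cand
    parent = _gini(float(y.mean()))
    if parent - best <= _GAIN_EPS:  # no real improvement
        return None
    return feature, threshold


def _best_split_newton(X: np.ndarray, g: np.ndarray, h: np.ndarray, lam: float):
    """Second-order (XGBoost-style) gain maximisation."""
    m = X.shape[0]
    if m < 2:
        return None
    order, xs, valid = _sorted_views(X)
    gl = np.cumsum(g[order], axis=0)
    hl = np.cumsum(h[order], axis=0)
    g_tot, h_tot = gl[-1], hl[-1]
    gl, hl = gl[:-1], hl[:-1]
    score_parent = g_tot**2 / (h_tot + lam)
    gain = gl**2 / (hl + lam) + (g_tot - gl) ** 2 / (h_tot - hl + lam) - score_parent
    gain = np.where(valid, gain, -np.inf)
    cand = _pick_candidate(gain, xs, maximize=True)
    if cand is None or cand[2] <= _GAIN_EPS:
        return None
    return cand[0], cand[1]


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------


def train_cart(X, y, cfg: TrainConfig | None = None) -> TreeModel:
    """Grow a probability-space classification tree by exact greedy Gini.

    Every node's value is the class-1 fraction of the training rows routed
    through it; impurity is the node's Gini index.  Deterministic: split
    candidates are midpoints of consecutive distinct sorted values, ties go
    to the lowest feature index then the lowest threshold.
    """
    cfg = cfg or TrainConfig()
    X, names = as_matrix(X)
    y = as_labels(y, require_both_classes=True)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")

    nodes: dict[int, TreeNode] = {}
    counter = 0

    def grow(idx: np.ndarray, depth: int) -> int:
        nonlocal counter
        nid = counter
        counter += 1
        ysub = y[idx]
        p1 = float(ysub.mean())
        node = TreeNode(
            node_id=nid, value=p1, n_samples=float(idx.size), impurity=_gini(p1)
        )
        nodes[nid] = node
        if (
            depth < cfg.max_depth
            and idx.size >= cfg.min_samples_split
            and 0.0 < p1 < 1.0
        ):
            cand = _best_split_gini(X[idx], ysub)
            if cand is not None:
                feature, threshold = cand
                go_left = X[idx, feature] <= threshold
                node.feature_index = feature
                node.threshold = threshold
                node.left = grow(idx[go_left], depth + 1)
                node.right = grow(idx[~go_left], depth + 1)
        return nid

    root = grow(np.arange(X.shape[0]), 0)
    return TreeModel(
        nodes=nodes,
        root_id=root,
        n_features=X.shape[1],
        feature_names=names,
        value_space=PROBABILITY,
    )


def _fill_internal_values(nodes: dict[int, TreeNode], root_id: int) -> None:
    """Set internal-node values to cover-weighted descendant-leaf means."""

    def rec(nid: int) -> tuple[float, float]:  # (cover, cover * mean value)
        node = nodes[nid]
        if node.is_leaf:
            return node.n_samples, node.n_samples * node.value
        cl, sl = rec(node.left)
        cr, sr = rec(node.right)
        cover, total = cl + cr, sl + sr
        node.value = total / cover if cover > 0 else 0.0
        return cover, total

    rec(root_id)


def train_boosted(X, y, cfg: TrainConfig | None = None) -> BoostedEnsemble:
    """Newton gradient boosting with logistic loss.

    Each round fits a margin tree to the gradient/hessian of the logistic
    loss at the current margin; leaf weights are ``-lr * G / (H + lambda)``.
    Internal node values — required by the path decomposition — are the
    cover-weighted means of descendant leaf weights, with cover the training
    row count routed through the node.  Node impurity records the label Gini
    so impurity-decrease importances remain available for ensembles.
    """
    cfg = cfg or TrainConfig()
    X, names = as_matrix(X)
    y = as_labels(y, require_both_classes=True)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    n = X.shape[0]
    base_score = 0.0
    margin_acc = np.full(n, base_score, dtype=np.float64)
    trees: list[TreeModel] = []

    for _ in range(cfg.n_trees):
        t = np.tanh(0.5 * margin_acc)
        # written so that complementing the labels negates g bitwise and
        # leaves h bitwise unchanged (exact class-symmetry downstream)
        g = 0.5 * t + (0.5 - y.astype(np.float64))
        h = 0.25 * (1.0 - t * t)

        nodes: dict[int, TreeNode] = {}
        counter = 0

        def grow(idx: np.ndarray, depth: int) -> int:
            nonlocal counter
            nid = counter
            counter += 1
            ysub = y[idx]
            node = TreeNode(
                node_id=nid,
                value=0.0,
                n_samples=float(idx.size),
                impurity=_gini(float(ysub.mean())),
            )
            nodes[nid] = node
            cand = None
            if depth < cfg.max_depth and idx.size >= cfg.min_samples_split:
                cand = _best_split_newton(X[idx], g[idx], h[idx], cfg.reg_lambda)
            if cand is None:
                w = -(cfg.learning_rate * g[idx].sum()) / (
                    h[idx].sum() + cfg.reg_lambda
                )
                node.value = float(w)
                margin_acc[idx] += w
            else:
                feature, threshold = cand
                go_left = X[idx, feature] <= threshold
                node.feature_index = feature
                node.threshold = threshold
                node.left = grow(idx[go_left], depth + 1)
                node.right = grow(idx[~go_left], depth + 1)
            return nid

        root = grow(np.arange(n), 0)
        _fill_internal_values(nodes, root)
        trees.append(
            TreeModel(
                nodes=nodes,
                root_id=root,
                n_features=X.shape[1],
                feature_names=names,
                value_space=MARGIN,
            )
        )

    return BoostedEnsemble(
        trees=trees, base_score=base_score, n_features=X.shape[1], feature_names=names
    )


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

_FDEFAULT = re.compile(r"^f(\d+)$")


def tree_to_json(tree: TreeModel) -> dict:
    """Mirrored single-tree schema: flat node list keyed by id."""
    return {
        "kind": "tree",
        "value_space": tree.value_space,
        "root_id": tree.root_id,
        "feature_names": list(tree.feature_names),
        "nodes": [
            {
                "id": n.node_id,
                "feature": None
                if n.is_leaf
                else tree.feature_names[n.feature_index],
                "threshold": n.threshold,
                "left": n.left,
                "right": n.right,
                "value": n.value,
                "n_samples": n.n_samples,
                "impurity": n.impurity,
            }
            for n in tree.nodes.values()
        ],
    }


def tree_from_json(obj: dict) -> TreeModel:
    names = [str(n) for n in obj["feature_names"]]
    index = {name: i for i, name in enumerate(names)}
    nodes = {}
    for rec in obj["nodes"]:
        feat = rec.get("feature")
        if feat is not None and feat not in index:
            raise ValueError(f"unknown feature name {feat!r}")
        nodes[rec["id"]] = TreeNode(
            node_id=rec["id"],
            value=rec["value"],
            n_samples=rec.get("n_samples", 0.0),
            feature_index=None if feat is None else index[feat],
            threshold=rec.get("threshold"),
            left=rec.get("left"),
            right=rec.get("right"),
            impurity=rec.get("impurity"),
        )
    return TreeModel(
        nodes=nodes,
        root_id=obj["root_id"],
        n_features=len(names),
        feature_names=names,
        value_space=obj.get("value_space", PROBABILITY),
    )


def _dump_tree_nodes(tree: TreeModel, nid: int) -> dict:
    node = tree.nodes[nid]
    if node.is_leaf:
        return {"nodeid": nid, "leaf": node.value, "cover": node.n_samples}
    # dialect semantics are "yes if x < cond"; our routing is "left if
    # x <= t".  nextafter makes the predicates identical and round-trips.
    cond = float(np.nextafter(node.threshold, np.inf))
    return {
        "nodeid": nid,
        "split": tree.feature_names[node.feature_index],
        "split_condition": cond,
        "yes": node.left,
        "no": node.right,
        "missing": node.left,
        "cover": node.n_samples,
        "children": [
            _dump_tree_nodes(tree, node.left),
            _dump_tree_nodes(tree, node.right),
        ],
    }


def export_model_dump(ens: BoostedEnsemble, path=None) -> dict:
    """Write an ensemble in the boosted-model JSON dump dialect.

    The wrapper object also records ``base_score`` and ``feature_names`` so
    the file re-imports without extra flags.
    """
    obj = {
        "kind": "boosted_ensemble",
        "base_score": ens.base_score,
        "feature_names": list(ens.feature_names),
        "trees": [_dump_tree_nodes(t, t.root_id) for t in ens.trees],
    }
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)
    return obj


def _import_dump_tree(root: dict, names: list[str], index: dict[str, int]) -> TreeModel:
    nodes: dict[int, TreeNode] = {}

    def rec(rec_obj: dict) -> tuple[float, float]:
        nid = rec_obj["nodeid"]
        if "leaf" in rec_obj:
            if "cover" not in rec_obj:
                raise ValueError(
                    "model dump lacks cover statistics; re-export the dump "
                    "with statistics (with_stats=True)"
                )
            cover = float(rec_obj["cover"])
            nodes[nid] = TreeNode(
                node_id=nid, value=float(rec_obj["leaf"]), n_samples=cover
            )
            return cover, cover * float(rec_obj["leaf"])
        split = rec_obj["split"]
        if split in index:
            fidx = index[split]
        else:
            m = _FDEFAULT.match(str(split))
            if m is None:
                raise ValueError(f"unknown feature name {split!r} in model dump")
            fidx = int(m.group(1))
            if fidx >= len(names):
                raise ValueError(f"unknown feature name {split!r} in model dump")
        children = {c["nodeid"]: c for c in rec_obj["children"]}
        cl, sl = rec(children[rec_obj["yes"]])
        cr, sr = rec(children[rec_obj["no"]])
        cover, total = cl + cr, sl + sr
        nodes[nid] = TreeNode(
            node_id=nid,
            value=total / cover if cover > 0 else 0.0,
            n_samples=cover,
            feature_index=fidx,
            threshold=float(np.nextafter(float(rec_obj["split_condition"]), -np.inf)),
            left=rec_obj["yes"],
            right=rec_obj["no"],
        )
        return cover, total

    rec(root)
    return TreeModel(
        nodes=nodes,
        root_id=root["nodeid"],
        n_features=len(names),
        feature_names=names,
        value_space=MARGIN,
    )


def import_model_dump(
    source, base_score: float | None = None, feature_names: Sequence[str] | None = None
) -> BoostedEnsemble:
    """Load a boosted ensemble from a JSON model dump.

    ``source`` may be a path, an already-parsed wrapper object
    (``{"base_score", "feature_names", "trees"}``) or a bare list of per-tree
    nested node objects.  Internal node values are reconstructed as
    cover-weighted means of descendant leaves.  ``base_score`` (log-odds) and
    ``feature_names`` passed as arguments override file metadata; the
    fallbacks are 0.0 and ``f0..f{d-1}`` names inferred from split indices.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, encoding="utf-8") as fh:
            source = json.load(fh)
    if isinstance(source, dict):
        tree_objs = source["trees"]
        if base_score is None:
            base_score = source.get("base_score")
        if feature_names is None:
            feature_names = source.get("feature_names")
    else:
        tree_objs = list(source)
    if base_score is None:
        base_score = 0.0
    if feature_names is None:
        n_feat = 0
        split_names: set[str] = set()

        def scan(rec_obj: dict):
            nonlocal n_feat
            if "leaf" in rec_obj:
                return
            split_names.add(str(rec_obj["split"]))
            m = _FDEFAULT.match(str(rec_obj["split"]))
            if m is not None:
                n_feat = max(n_feat, int(m.group(1)) + 1)
            for c in rec_obj["children"]:
                scan(c)

        for t in tree_objs:
            scan(t)
        unnumbered = [s for s in split_names if _FDEFAULT.match(s) is None]
        if unnumbered:
            raise ValueError(
                "model dump uses feature names "
                f"{sorted(unnumbered)!r}; pass feature_names= to resolve them"
            )
        feature_names = [f"f{i}" for i in range(max(n_feat, 1))]
    names = [str(n) for n in feature_names]
    index = {name: i for i, name in enumerate(names)}
    trees = [_import_dump_tree(t, names, index) for t in tree_objs]
    return BoostedEnsemble(
        trees=trees,
        base_score=float(base_score),
        n_features=len(names),
        feature_names=names,
    )
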