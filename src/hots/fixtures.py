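"""Self-contained inputs: a worked-example tree, iris, synthetic tables.

Three sources of data with known structure:

* :func:`worked_example_tree` — a small hand-specified probability tree
  whose prediction path for a fixed probe sample exercises repeated splits
  on one feature, used to pin down the path-decomposition arithmetic;
* :func:`make_synthetic` — Gaussian tables with planted, directionally
  known class-mean shifts on chosen features, the ground truth for recovery
  tests;
* :func:`iris_binary` — the canonical 100-row versicolor/virginica subset
  of Anderson's iris data (versicolor = 0, virginica = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree_core import TreeModel, TreeNode

__all__ = [
    "SyntheticSpec",
    "worked_example_tree",
    "make_synthetic",
    "iris_binary",
]


@dataclass
class SyntheticSpec:
    """Recipe for a planted-signal binary-classification table.

    ``informative`` lists ``(feature_index, mean_shift)`` pairs; the shift
    is the class-1 mean minus the class-0 mean in units of the noise sd, so
    its sign is the planted direction.  All other features are pure noise.
    """

    n_samples: int = 500
    n_features: int = 10
    informative: list[tuple[int, float]] = field(default_factory=lambda: [(0, 3.0)])
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        idx = [i for i, _ in self.informative]
        if len(set(idx)) != len(idx):
            raise ValueError("informative feature indices must be unique")
        if any(not 0 <= i < self.n_features for i in idx):
            raise ValueError("informative feature index out of range")


def worked_example_tree() -> tuple[TreeModel, np.ndarray]:
    """Depth-4 probability tree with a fully pinned-down prediction path.

    The probe sample (sepal length 6.9, sepal width 3.1, petal length 4.9)
    walks node values 0.493 (root) -> 0.051 -> 0.25 -> 0.143 -> 1.0,
    splitting on petal length twice, then sepal width, then sepal length,
    so its decomposition is petal length (0.051-0.493)+(0.25-0.051) =
    -0.243, sepal width 0.143-0.25 = -0.107, sepal length 1.0-0.143 =
    +0.857, bias 0.493, predicted probability exactly 1.0.  Off-path
    children are leaves carrying their parent's value, so branches not
    taken are fully specified without affecting the probe's arithmetic.
    """
    names = ["sepal length (cm)", "sepal width (cm)", "petal length (cm)"]
    N = TreeNode
    nodes = {
        0: N(0, value=0.493, n_samples=100, feature_index=2, threshold=5.0,
             left=1, right=2),
        1: N(1, value=0.051, n_samples=70, feature_index=2, threshold=4.95,
             left=3, right=4),
        2: N(2, value=0.493, n_samples=30),
        3: N(3, value=0.25, n_samples=20, feature_index=1, threshold=3.15,
             left=5, right=6),
        4: N(4, value=0.051, n_samples=50),
        5: N(5, value=0.143, n_samples=14, feature_index=0, threshold=6.0,
             left=7, right=8),
        6: N(6, value=0.25, n_samples=6),
        7: N(7, value=0.143, n_samples=7),
        8: N(8, value=1.0, n_samples=7),
    }
    tree = TreeModel(
        nodes=nodes,
        root_id=0,
        n_features=3,
        feature_names=names,
        value_space="probability",
    )
    probe = np.array([6.9, 3.1, 4.9])
    return tree, probe


def make_synthetic(spec: SyntheticSpec | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a planted-signal table; deterministic per spec + seed.

    Labels are Bernoulli(class_balance); every feature is Gaussian noise
    with sd ``noise_sd``, and each informative feature's class-1 rows are
    shifted by ``mean_shift * noise_sd``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_samples) < spec.class_balance).astype(np.int8)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
    for idx, shift in spec.informative:
        X[y == 1, idx] += shift * spec.noise_sd
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(spec.n_features)])
    return frame, y


def iris_binary() -> tuple[pd.DataFrame, np.ndarray]:
    """The binarised iris table: versicolor (0) vs virginica (1), 100 x 4.

    Setosa is dropped to make the problem binary.  Loaded from
    scikit-learn's bundled copy of the canonical dataset.
    """
    from sklearn.datasets import load_iris

    data = load_iris(as_frame=True)
    frame = data.frame
    keep = frame["target"].isin([1, 2])
    X = frame.loc[keep, data.feature_names].reset_index(drop=True)
    y = (frame.loc[keep, "target"] == 2).to_numpy().astype(np.int8)
    return X, y
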