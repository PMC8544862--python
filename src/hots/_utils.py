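"""Shared input coercion and numeric helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["as_matrix", "as_labels", "sigmoid"]


def as_matrix(X, feature_names=None):
    """Coerce a feature table to a float64 matrix plus feature names.

    Accepts a pandas DataFrame (names taken from columns), a numpy array or
    nested sequences (names default to ``f0..f{d-1}``).  Missing or
    non-finite cells are rejected: none of the models here define a routing
    rule for missing values.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        values = X.to_numpy()
    else:
        names = None
        values = np.asarray(X)
    try:
        values = np.asarray(values, dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature value in table: {exc}") from exc
    if values.ndim == 1:
        values = values.reshape(1, -1)
    if values.ndim != 2:
        raise ValueError(f"feature table must be 2-D, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("feature table contains missing or non-finite values")
    if feature_names is not None:
        names = [str(n) for n in feature_names]
    if names is None:
        names = [f"f{i}" for i in range(values.shape[1])]
    if len(names) != values.shape[1]:
        raise ValueError(
            f"{len(names)} feature names for {values.shape[1]} columns"
        )
    return values, names


def as_labels(y, require_both_classes=False):
    """Coerce labels to an int8 0/1 vector."""
    if isinstance(y, (pd.Series, pd.DataFrame)):
        y = np.asarray(y).squeeze()
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError(f"labels must be 1-D, got shape {y.shape}")
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got values {vals!r}")
    if require_both_classes and len(vals) < 2:
        raise ValueError("degenerate labels: only one class present")
    return y.astype(np.int8)


def sigmoid(margin):
    """Logistic function, written odd-symmetrically.

    ``(1 + tanh(m/2)) / 2`` rather than ``1/(1+exp(-m))`` so that
    ``sigmoid(-m)`` is the bitwise complement of ``sigmoid(m)``; downstream
    gradient statistics then negate exactly under label complement, which
    keeps class-symmetry properties of the pipeline exact instead of
    approximate.
    """
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(margin, dtype=np.float64)))
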