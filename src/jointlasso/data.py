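"""Grouped data model: subgroup splitting, standardization, prediction, I/O.

The joint lasso operates on K per-subgroup regression problems
``(X_k, y_k)`` sharing the same p features.  Features and responses are
standardized *within each subgroup* so that no intercepts are needed;
the standardization statistics are retained so that predictions can be
returned on the original response scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .base import FitResult


@dataclass
class GroupStats:
    """Per-subgroup standardization statistics (original scale)."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float


@dataclass
class GroupedDataset:
    """Samples partitioned into K subgroups sharing p features.

    ``X[k]`` is the ``n_k x p`` feature matrix and ``y[k]`` the response
    vector of subgroup ``k``.  When ``standardized`` is True every feature
    column and the response have mean 0 and unit scale within each subgroup,
    and ``stats[k]`` holds the original-scale means and scales (population
    standard deviations) needed to undo the transform.
    """

    X: list[np.ndarray]
    y: list[np.ndarray]
    group_names: list[str]
    feature_names: list[str]
    stats: list[GroupStats] | None = None
    standardized: bool = False

    @property
    def K(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X[0].shape[1]

    @property
    def n_k(self) -> np.ndarray:
        return np.array([len(yk) for yk in self.y])

    @property
    def n(self) -> int:
        return int(self.n_k.sum())

    def group_index(self, name) -> int:
        try:
            return self.group_names.index(name)
        except ValueError:
            raise KeyError(f"unknown subgroup label {name!r}") from None

    def raw_X(self, k: int) -> np.ndarray:
        """Feature matrix of subgroup ``k`` on the original scale."""
        if not self.standardized:
            return self.X[k]
        s = self.stats[k]
        return self.X[k] * s.x_scale + s.x_mean

    def raw_y(self, k: int) -> np.ndarray:
        """Response of subgroup ``k`` on the original scale."""
        if not self.standardized:
            return self.y[k]
        s = self.stats[k]
        return self.y[k] * s.y_scale + s.y_mean

    def to_arrays(self, raw: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate all subgroups into ``(X, y, labels)`` arrays.

        Rows are ordered by subgroup, subgroups in ``group_names`` order.
        """
        if raw:
            Xs = [self.raw_X(k) for k in range(self.K)]
            ys = [self.raw_y(k) for k in range(self.K)]
        else:
            Xs, ys = self.X, self.y
        labels = np.concatenate(
            [np.repeat(self.group_names[k], len(ys[k])) for k in range(self.K)]
        )
        return np.vstack(Xs), np.concatenate(ys), labels


def split_by_group(X, y, labels, feature_names=None) -> GroupedDataset:
    """Partition samples into subgroups by label.

    Subgroups are ordered lexicographically by label so that the grouping
    is deterministic.  Every subgroup must contain at least two samples.
    """
    X = np.asarray(X)
    if not np.issubdtype(X.dtype, np.number):
        raise ValueError("features must be numeric")
    X = X.astype(float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if len(y) != X.shape[0] or len(labels) != X.shape[0]:
        raise ValueError("X, y and labels must have the same number of rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported; remove or impute upstream")

    names = sorted(np.unique(labels).tolist())
    Xs, ys = [], []
    for name in names:
        mask = labels == name
        if mask.sum() < 2:
            raise ValueError(f"subgroup {name!r} has fewer than 2 samples")
        Xs.append(X[mask])
        ys.append(y[mask])
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return GroupedDataset(Xs, ys, [str(n) for n in names], list(feature_names))


def standardize_subgroups(ds: GroupedDataset) -> GroupedDataset:
    """Center and scale features and response within each subgroup.

    Uses population standard deviations (divide by ``n_k``), consistent
    with the ``1/n_k`` loss normalization.  The original-scale statistics
    are stored on the returned dataset so predictions can be
    back-transformed.  Constant columns are rejected: silently dropping a
    column in one subgroup would desynchronize feature indexing across
    subgroups.
    """
    Xs, ys, stats = [], [], []
    for k in range(ds.K):
        Xk = ds.raw_X(k)
        yk = ds.raw_y(k)
        x_mean = Xk.mean(axis=0)
        x_scale = Xk.std(axis=0)
        bad = np.flatnonzero(x_scale == 0)
        if bad.size:
            cols = ", ".join(ds.feature_names[j] for j in bad[:5])
            raise ValueError(
                f"feature(s) {cols} constant within subgroup {ds.group_names[k]!r}"
            )
        y_mean = yk.mean()
        y_scale = yk.std()
        if y_scale == 0:
            raise ValueError(f"response constant within subgroup {ds.group_names[k]!r}")
        Xs.append((Xk - x_mean) / x_scale)
        ys.append((yk - y_mean) / y_scale)
        stats.append(GroupStats(x_mean, x_scale, float(y_mean), float(y_scale)))
    return GroupedDataset(
        Xs, ys, list(ds.group_names), list(ds.feature_names), stats, standardized=True
    )


def predict(ds: GroupedDataset, B: np.ndarray, X_new, groups_new) -> np.ndarray:
    """Predict responses (original scale) for new raw-scale samples.

    Each new row is standardized with its assigned subgroup's stored
    statistics, multiplied into that subgroup's coefficient vector, and the
    result is mapped back to the original response scale.
    """
    if not ds.standardized or ds.stats is None:
        raise ValueError("dataset must be standardized (call standardize_subgroups)")
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    B = np.asarray(B, dtype=float)
    if B.shape != (ds.p, ds.K):
        raise ValueError(f"B must be {ds.p} x {ds.K}, got {B.shape}")
    groups_new = np.asarray(groups_new)
    out = np.empty(X_new.shape[0])
    for name in np.unique(groups_new):
        k = ds.group_index(name)
        s = ds.stats[k]
        mask = groups_new == name
        Z = (X_new[mask] - s.x_mean) / s.x_scale
        out[mask] = Z @ B[:, k] * s.y_scale + s.y_mean
    return out


def read_dataset(path, response: str, group: str):
    """Read a delimited table; return ``(X, y, labels, feature_names)``.

    All columns other than the designated response and group columns are
    treated as numeric features.  Row order is preserved.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (response, group):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    feats = [c for c in df.columns if c not in (response, group)]
    X = df[feats].to_numpy()
    if not np.issubdtype(X.dtype, np.number):
        raise ValueError("all feature columns must be numeric")
    return X, df[response].to_numpy(dtype=float), df[group].to_numpy(), feats


def write_coefficients(path, fit: FitResult, extra_meta: dict | None = None) -> None:
    """Write a fitted coefficient matrix as CSV plus a YAML metadata sidecar.

    The CSV has one row per feature and one column per subgroup.  The
    sidecar (``<path>.meta.yaml``) records the tuning parameters, solver
    and convergence status for provenance.
    """
    path = Path(path)
    feats = fit.feature_names or [f"x{j}" for j in range(fit.B.shape[0])]
    groups = fit.group_names or [f"g{k}" for k in range(fit.B.shape[1])]
    pd.DataFrame(fit.B, index=feats, columns=groups).to_csv(path, index_label="feature")
    meta = {
        "lambda": float(fit.spec.lam),
        "gamma": float(fit.spec.gamma),
        "tau_mode": fit.spec.mode,
        "solver": fit.solver,
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
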