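"""Data-driven pairwise fusion weights tau.

Instead of cross-validating every pair weight, tau can be set in advance
from a distance ``d(k, k')`` between the subgroups' feature distributions:
either the Euclidean distance between subgroup feature means, or the
symmetrised Kullback-Leibler divergence between per-subgroup multivariate
Gaussian models (covariances estimated with the graphical lasso).  Weights
are mapped to the unit interval via ``tau = 1 - d / d_max``, so the most
distant pair gets 0 and identical subgroups get 1.

Distances are computed on globally standardized features (pooled mean 0,
unit scale): per-subgroup standardization would erase exactly the mean
differences the weighting is meant to capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import GraphicalLasso

from .data import GroupedDataset


@dataclass
class SubgroupModel:
    """Gaussian model of one subgroup's feature distribution."""

    mu: np.ndarray
    sigma: np.ndarray
    precision: np.ndarray | None = None


def _pooled_standardized(ds: GroupedDataset) -> list[np.ndarray]:
    """Raw per-subgroup features rescaled to pooled mean 0 / unit scale."""
    Xs = [ds.raw_X(k) for k in range(ds.K)]
    allX = np.vstack(Xs)
    mean = allX.mean(axis=0)
    scale = allX.std(axis=0)
    scale[scale == 0] = 1.0
    return [(X - mean) / scale for X in Xs]


def _tau_from_distances(d: np.ndarray, context: str) -> np.ndarray:
    K = d.shape[0]
    d_max = d.max()
    if d_max == 0:
        warnings.warn(
            f"{context}: all subgroup distances are zero; falling back to "
            "unweighted fusion (tau = 1)"
        )
        return np.ones((K, K)) - np.eye(K)
    tau = 1.0 - d / d_max
    np.fill_diagonal(tau, 0.0)
    if K == 2:
        warnings.warn(
            "with K=2 the single pair attains d_max, forcing tau=0 "
            "(fusion disabled); weighted modes are intended for K >= 3"
        )
    return tau


def tau_from_means(ds: GroupedDataset) -> np.ndarray:
    """Pair weights from distances between subgroup feature means."""
    if ds.K < 2:
        raise ValueError("tau weighting requires K >= 2")
    Xs = _pooled_standardized(ds)
    mus = np.array([X.mean(axis=0) for X in Xs])
    diff = mus[:, None, :] - mus[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    return _tau_from_distances(d, "tau_from_means")


def symmetrised_kl_gaussian(model_k: SubgroupModel, model_l: SubgroupModel) -> float:
    """Symmetrised KL divergence between two multivariate Gaussians.

    ``d = (KL(p_k||p_l) + KL(p_l||p_k)) / 2`` using the closed form
    ``KL(N0||N1) = (tr(S1^-1 S0) + (m1-m0)'S1^-1(m1-m0) - p + ln det S1/det S0)/2``.
    """

    def _kl(m0, S0, m1, S1):
        p = len(m0)
        sign1, logdet1 = np.linalg.slogdet(S1)
        sign0, logdet0 = np.linalg.slogdet(S0)
        if sign1 <= 0 or sign0 <= 0:
            raise ValueError(
                "singular covariance estimate; increase regularization"
            )
        S1_inv = np.linalg.inv(S1)
        dm = m1 - m0
        return 0.5 * (
            np.trace(S1_inv @ S0) + dm @ S1_inv @ dm - p + logdet1 - logdet0
        )

    a = _kl(model_k.mu, model_k.sigma, model_l.mu, model_l.sigma)
    b = _kl(model_l.mu, model_l.sigma, model_k.mu, model_k.sigma)
    return float(0.5 * (a + b))


def fit_subgroup_models(
    ds: GroupedDataset, cov_regularization: float = 0.1, jitter: float = 1e-6
) -> list[SubgroupModel]:
    """Fit a Gaussian per subgroup with graphical-lasso covariance.

    ``cov_regularization`` is the l1 penalty on the precision matrix (on
    globally standardized data); a ``jitter * I`` ridge is added to the
    covariance before use since p may exceed n_k.
    """
    Xs = _pooled_standardized(ds)
    models = []
    for k, X in enumerate(Xs):
        try:
            gl = GraphicalLasso(alpha=cov_regularization, assume_centered=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gl.fit(X)
            sigma = gl.covariance_ + jitter * np.eye(ds.p)
            prec = gl.precision_
        except Exception as exc:  # noqa: BLE001 - re-raised with subgroup context
            raise RuntimeError(
                f"covariance estimation failed for subgroup "
                f"{ds.group_names[k]!r}: {exc}"
            ) from exc
        models.append(SubgroupModel(mu=X.mean(axis=0), sigma=sigma, precision=prec))
    return models


def tau_from_kl(
    ds: GroupedDataset, cov_regularization: float = 0.1, jitter: float = 1e-6
) -> np.ndarray:
    """Pair weights from symmetrised KL between fitted Gaussian models."""
    if ds.K < 2:
        raise ValueError("tau weighting requires K >= 2")
    models = fit_subgroup_models(ds, cov_regularization, jitter)
    K = ds.K
    d = np.zeros((K, K))
    for k in range(K):
        for l in range(k + 1, K):
            d[k, l] = d[l, k] = symmetrised_kl_gaussian(models[k], models[l])
    return _tau_from_distances(d, "tau_from_kl")
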