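"""Joint lasso with l2 (ridge-type) fusion.

The criterion minimized over the ``p x K`` coefficient matrix
``B = [beta_1 ... beta_K]`` is

    sum_k { (1/n_k) ||y_k - X_k beta_k||_2^2 + lambda ||beta_k||_1
            + gamma sum_{k'>k} tau_{k,k'} ||beta_k - beta_{k'}||_2^2 }

Each unordered subgroup pair is counted once.  Because the fusion term is
quadratic, each coordinate has a closed-form minimizer (a soft-thresholded
ridge update), giving a monotone cyclic coordinate-descent solver.  The same
problem can also be rewritten as one classical lasso on an augmented design
(block-diagonal X with fusion-difference rows appended), which a standard
lasso solver handles efficiently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import lsqr
from sklearn.linear_model import Lasso

from .base import FitResult, FusionSpec
from .data import GroupedDataset


def _check_B(B, ds: GroupedDataset) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.shape != (ds.p, ds.K):
        raise ValueError(f"B must be {ds.p} x {ds.K}, got {B.shape}")
    return B


def objective_l2(B, ds: GroupedDataset, spec: FusionSpec) -> float:
    """Evaluate the l2-fusion joint-lasso objective at ``B``."""
    B = _check_B(B, ds)
    tau = spec.tau_matrix(ds.K)
    val = 0.0
    for k in range(ds.K):
        r = ds.y[k] - ds.X[k] @ B[:, k]
        val += r @ r / ds.n_k[k] + spec.lam * np.abs(B[:, k]).sum()
        for k2 in range(k + 1, ds.K):
            d = B[:, k] - B[:, k2]
            val += spec.gamma * tau[k, k2] * (d @ d)
    return float(val)


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def coordinate_update(j, k, B, ds: GroupedDataset, spec: FusionSpec) -> float:
    """Exact single-coordinate minimizer of the objective in ``beta_{j,k}``.

    First the ridge-type optimum ignoring the l1 penalty,

        beta* = [x_j' r + n_k g S] / [x_j' x_j + n_k g T],

    with ``r`` the partial residual excluding feature ``j``,
    ``S = sum_{k'!=k} tau_{k,k'} beta_{j,k'}``, ``T = sum_{k'!=k} tau_{k,k'}``
    and ``g = gamma``; the l1 penalty then soft-thresholds ``beta*`` by
    ``lambda n_k / (2 [x_j' x_j + n_k g T])``, the amount implied by the
    subgradient stationarity condition.
    """
    B = _check_B(B, ds)
    tau = spec.tau_matrix(ds.K)
    x = ds.X[k][:, j]
    r = ds.y[k] - ds.X[k] @ B[:, k] + x * B[j, k]
    others = [k2 for k2 in range(ds.K) if k2 != k]
    S = sum(tau[k, k2] * B[j, k2] for k2 in others)
    T = sum(tau[k, k2] for k2 in others)
    nk = ds.n_k[k]
    den = x @ x + nk * spec.gamma * T
    if den == 0.0:
        warnings.warn(f"zero curvature for coordinate ({j}, {k}); returning 0")
        return 0.0
    num = x @ r + nk * spec.gamma * S
    return _soft(num / den, spec.lam * nk / (2.0 * den))


def fit_l2_cd(
    ds: GroupedDataset,
    spec: FusionSpec,
    tol: float = 1e-5,
    max_iter: int = 1000,
    B_init: np.ndarray | None = None,
) -> FitResult:
    """Cyclic coordinate descent for the l2-fusion joint lasso.

    Sweeps coordinates feature-major within each subgroup, subgroups in
    order, until the largest absolute coefficient change in a sweep drops
    below ``tol``.  Exact coordinate minimization guarantees the objective
    is non-increasing sweep to sweep.
    """
    if not ds.standardized:
        warnings.warn("dataset does not appear to be standardized")
    K, p = ds.K, ds.p
    if K == 1 and spec.gamma > 0:
        warnings.warn("K=1: fusion penalty has no effect")
    tau = spec.tau_matrix(K)
    B = np.zeros((p, K)) if B_init is None else _check_B(B_init, ds).copy()

    col_sq = [np.einsum("ij,ij->j", ds.X[k], ds.X[k]) for k in range(K)]
    resid = [ds.y[k] - ds.X[k] @ B[:, k] for k in range(K)]
    T = tau.sum(axis=1)  # row sums; diagonal is zero
    nk = ds.n_k

    trace = [objective_l2(B, ds, spec)]
    if not np.isfinite(trace[0]):
        raise ValueError("non-finite objective; check input scaling")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        for k in range(K):
            Xk = ds.X[k]
            den_fuse = nk[k] * spec.gamma * T[k]
            thr_base = spec.lam * nk[k] / 2.0
            for j in range(p):
                old = B[j, k]
                x = Xk[:, j]
                den = col_sq[k][j] + den_fuse
                if den == 0.0:
                    new = 0.0
                else:
                    S = tau[k] @ B[j] - tau[k, k] * B[j, k]  # excludes k (diag 0)
                    num = x @ resid[k] + col_sq[k][j] * old + nk[k] * spec.gamma * S
                    new = _soft(num, thr_base) / den
                if new != old:
                    resid[k] += x * (old - new)
                    B[j, k] = new
                    delta = max(delta, abs(new - old))
        trace.append(objective_l2(B, ds, spec))
        if delta < tol:
            converged = True
            break
    return FitResult(
        B=B,
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        solver="l2-cd",
        spec=spec,
        group_names=list(ds.group_names),
        feature_names=list(ds.feature_names),
    )


def lambda_max(ds: GroupedDataset) -> float:
    """Smallest l1 weight at which ``B = 0`` solves the joint lasso.

    At ``B = 0`` the fusion penalty vanishes, so the null solution is
    stationary iff ``2 |x_j' y_k| / n_k <= lambda`` for every coordinate.
    """
    return max(
        2.0 * np.abs(ds.X[k].T @ ds.y[k]).max() / ds.n_k[k] for k in range(ds.K)
    )


@dataclass
class AugmentedProblem:
    """Classical-lasso reformulation of the l2-fusion problem.

    ``X_aug`` stacks the block-diagonal per-subgroup design (block ``k``
    scaled by ``1/sqrt(n_k)`` to preserve the ``1/n_k`` loss weights) over
    fusion rows ``Gamma``; ``y_aug`` is the correspondingly scaled response
    stacked over zeros.  Flat coefficient position ``k*p + j`` maps to
    feature ``j`` of subgroup ``k``.
    """

    X_aug: sparse.spmatrix
    y_aug: np.ndarray
    p: int
    K: int
    spec: FusionSpec

    @property
    def shape(self):
        return self.X_aug.shape

    def unflatten(self, b_flat: np.ndarray) -> np.ndarray:
        return np.asarray(b_flat).reshape(self.K, self.p).T


def build_fusion_rows(p: int, K: int, spec: FusionSpec) -> sparse.csr_matrix:
    """Fusion-constraint rows Gamma of the augmented design.

    One block of ``p`` rows per unordered subgroup pair ``(k, k')``; row
    ``m`` of the block carries ``+c`` at flat position ``k*p + m`` and
    ``-c`` at ``k'*p + m`` with ``c = sqrt(gamma * tau_{k,k'})``, so that
    ``||Gamma b||_2^2`` reproduces the fusion term of the objective exactly.
    """
    if K < 2:
        raise ValueError("fusion rows require K >= 2")
    tau = spec.tau_matrix(K)
    rows, cols, vals = [], [], []
    r = 0
    for k in range(K):
        for k2 in range(k + 1, K):
            c = np.sqrt(spec.gamma * tau[k, k2])
            for m in range(p):
                if c > 0:
                    rows += [r, r]
                    cols += [k * p + m, k2 * p + m]
                    vals += [c, -c]
                r += 1
    n_rows = p * K * (K - 1) // 2
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_rows, p * K)
    )


def build_augmented(ds: GroupedDataset, spec: FusionSpec) -> AugmentedProblem:
    """Assemble the augmented design and response for the flat lasso."""
    if ds.K < 2:
        raise ValueError("augmented reformulation requires K >= 2")
    blocks = [sparse.csr_matrix(ds.X[k] / np.sqrt(ds.n_k[k])) for k in range(ds.K)]
    X_diag = sparse.block_diag(blocks, format="csr")
    Gamma = build_fusion_rows(ds.p, ds.K, spec)
    X_aug = sparse.vstack([X_diag, Gamma], format="csc")
    y_aug = np.concatenate(
        [ds.y[k] / np.sqrt(ds.n_k[k]) for k in range(ds.K)]
        + [np.zeros(Gamma.shape[0])]
    )
    return AugmentedProblem(X_aug=X_aug, y_aug=y_aug, p=ds.p, K=ds.K, spec=spec)


def fit_l2_augmented(
    ds: GroupedDataset,
    spec: FusionSpec,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    B_init: np.ndarray | None = None,
    problem: AugmentedProblem | None = None,
) -> FitResult:
    """Solve the l2-fusion joint lasso via the augmented classical lasso.

    The flat problem ``min ||y_aug - X_aug b||^2 + lambda ||b||_1`` is
    handed to scikit-learn's coordinate-descent lasso with the l1 weight
    rescaled to that solver's ``1/(2 n_samples)`` loss convention.  With
    ``lambda = 0`` the augmented system is solved by sparse least squares.
    Correctness is defined by agreement with :func:`fit_l2_cd`.
    """
    prob = problem if problem is not None else build_augmented(ds, spec)
    N = prob.shape[0]
    if spec.lam == 0.0:
        res = lsqr(prob.X_aug, prob.y_aug, atol=1e-12, btol=1e-12, iter_lim=10 * N)
        b, n_iter, converged = res[0], int(res[2]), res[1] in (1, 2)
    else:
        model = Lasso(
            alpha=spec.lam / (2.0 * N),
            fit_intercept=False,
            tol=tol,
            max_iter=max_iter,
            warm_start=B_init is not None,
        )
        if B_init is not None:
            model.coef_ = np.asarray(B_init, dtype=float).T.ravel().copy()
            model.intercept_ = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence reported via FitResult
            model.fit(prob.X_aug, prob.y_aug)
        b = model.coef_
        n_iter = int(np.max(model.n_iter_))
        converged = n_iter < max_iter
    B = prob.unflatten(b)
    return FitResult(
        B=B,
        objective_trace=np.asarray([objective_l2(B, ds, spec)]),
        n_iter=n_iter,
        converged=converged,
        solver="l2-augmented",
        spec=spec,
        group_names=list(ds.group_names),
        feature_names=list(ds.feature_names),
    )


def kkt_violation(B, ds: GroupedDataset, spec: FusionSpec) -> float:
    """Largest violation of the subgradient stationarity conditions at ``B``.

    For a nonzero coefficient the gradient of the smooth part plus
    ``lambda * sign(beta)`` must vanish; for a zero coefficient the smooth
    gradient must lie in ``[-lambda, lambda]``.  Returns the maximum excess
    over all coordinates (0 at an exact solution).
    """
    B = _check_B(B, ds)
    tau = spec.tau_matrix(ds.K)
    worst = 0.0
    for k in range(ds.K):
        r = ds.X[k] @ B[:, k] - ds.y[k]
        g = 2.0 * ds.X[k].T @ r / ds.n_k[k]
        fuse = 2.0 * spec.gamma * (tau[k].sum() * B[:, k] - B @ tau[k])
        g = g + fuse
        nz = B[:, k] != 0
        if nz.any():
            worst = max(worst, np.abs(g[nz] + spec.lam * np.sign(B[nz, k])).max())
        if (~nz).any():
            worst = max(worst, max(0.0, np.abs(g[~nz]).max() - spec.lam))
    return float(worst)
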