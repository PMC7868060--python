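"""Independent reference solvers used to certify the package's optimizers.

These deliberately avoid the package's own solution paths: the l2-fusion
objective is minimized by L-BFGS-B after splitting each coefficient into
positive and negative parts (which makes the objective smooth on the
nonnegative orthant), and the l1-fusion objective by SLSQP with auxiliary
variables bounding the absolute values.  Both operate on tiny instances
only.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from jointlasso.base import FusionSpec
from jointlasso.data import GroupedDataset


def _unpack(ds):
    return ds.K, ds.p, [np.asarray(X) for X in ds.X], [np.asarray(y) for y in ds.y]


def solve_l2_reference(ds: GroupedDataset, spec: FusionSpec) -> np.ndarray:
    """Minimize the l2-fusion objective with L-BFGS-B on a +/- split."""
    K, p, Xs, ys = _unpack(ds)
    tau = spec.tau_matrix(K)
    nk = ds.n_k

    def fun(z):
        ab = z.reshape(2, p, K)
        B = ab[0] - ab[1]
        val = spec.lam * (ab[0].sum() + ab[1].sum())
        G = np.zeros((p, K))
        for k in range(K):
            r = Xs[k] @ B[:, k] - ys[k]
            val += r @ r / nk[k]
            G[:, k] = 2.0 / nk[k] * (Xs[k].T @ r)
            for k2 in range(k + 1, K):
                d = B[:, k] - B[:, k2]
                val += spec.gamma * tau[k, k2] * (d @ d)
        # fusion gradient
        deg = tau.sum(axis=1)
        G += 2.0 * spec.gamma * (B * deg - B @ tau)
        grad = np.concatenate([(G + spec.lam).ravel(), (-G + spec.lam).ravel()])
        return val, grad

    z0 = np.zeros(2 * p * K)
    res = optimize.minimize(
        fun, z0, jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * len(z0),
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    ab = res.x.reshape(2, p, K)
    return ab[0] - ab[1]


def solve_l1_reference(ds: GroupedDataset, spec: FusionSpec) -> np.ndarray:
    """Minimize the l1-fusion objective with SLSQP and absolute-value slacks.

    Variables are ``(B, t, u)`` with ``|B| <= t`` elementwise and
    ``|beta_m - beta_l| <= u_e`` per fusion pair; the objective
    ``loss + lam * sum(t) + gamma * sum_e tau_e sum(u_e)`` is smooth and
    the constraints linear.
    """
    K, p, Xs, ys = _unpack(ds)
    tau = spec.tau_matrix(K)
    nk = ds.n_k
    pairs = [(k, l) for k in range(K) for l in range(k + 1, K) if tau[k, l] > 0]
    nB, nT = p * K, p * K
    nU = p * len(pairs)

    def split(z):
        return (
            z[:nB].reshape(p, K, order="F"),
            z[nB:nB + nT],
            z[nB + nT:],
        )

    def fun(z):
        B, t, u = split(z)
        val = spec.lam * t.sum()
        for e, (k, l) in enumerate(pairs):
            val += spec.gamma * tau[k, l] * u[e * p:(e + 1) * p].sum()
        for k in range(K):
            r = Xs[k] @ B[:, k] - ys[k]
            val += r @ r / nk[k]
        return val

    cons = []

    def abs_cons(z):
        B, t, _ = split(z)
        b = B.ravel(order="F")
        return np.concatenate([t - b, t + b])

    cons.append({"type": "ineq", "fun": abs_cons})

    if pairs:
        def diff_cons(z):
            B, _, u = split(z)
            out = []
            for e, (k, l) in enumerate(pairs):
                d = B[:, k] - B[:, l]
                ue = u[e * p:(e + 1) * p]
                out.append(ue - d)
                out.append(ue + d)
            return np.concatenate(out)

        cons.append({"type": "ineq", "fun": diff_cons})

    z0 = np.zeros(nB + nT + nU)
    res = optimize.minimize(
        fun, z0, method="SLSQP", constraints=cons,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    B, _, _ = split(res.x)
    return B


def sklearn_lasso(X, y, lam):
    """Reference classical lasso for ``(1/n)||y - Xb||^2 + lam ||b||_1``."""
    from sklearn.linear_model import Lasso

    model = Lasso(alpha=lam / 2.0, fit_intercept=False, tol=1e-12, max_iter=1_000_000)
    model.fit(X, y)
    return model.coef_.copy()
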