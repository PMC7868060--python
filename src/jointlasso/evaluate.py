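"""Metrics, cross-validated tuning and baseline comparisons.

Prediction error is reported as weighted RMSE: per-subgroup RMSEs combined
with weights ``n_k / n``, so small subgroups are not drowned out by large
ones.  Support recovery is scored as the AUROC of ranking all coefficients
by absolute fitted magnitude against the indicator of truly nonzero
coefficients.  Tuning of ``(lambda, gamma)`` is by subgroup-stratified
k-fold cross-validation minimizing mean held-out weighted RMSE; the
baselines are the pooled classical lasso (all subgroups merged) and the
subgroup-wise lasso (gamma = 0, independent fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .base import FitResult, FusionSpec
from .data import GroupedDataset, predict, split_by_group, standardize_subgroups
from .l1 import fit_l1_proximal
from .l2 import build_augmented, fit_l2_augmented, lambda_max


def weighted_rmse(predictions, observations, group_labels) -> float:
    """Subgroup-size-weighted root mean squared error.

    ``sum_k (n_k / n) * RMSE_k`` over the subgroups present in
    ``group_labels``.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    labels = np.asarray(group_labels)
    if not (len(pred) == len(obs) == len(labels)):
        raise ValueError("predictions, observations and labels must align")
    if len(pred) == 0:
        raise ValueError("empty input")
    total = 0.0
    n = len(pred)
    for name in np.unique(labels):
        mask = labels == name
        err = pred[mask] - obs[mask]
        total += (mask.sum() / n) * np.sqrt(np.mean(err**2))
    return float(total)


def support_auroc(B_hat, B_true) -> float:
    """AUROC of |fitted coefficient| as a score for true support membership.

    Ties in the ranking are handled by midranks (trapezoidal AUROC), so an
    all-zero estimate scores exactly 0.5.
    """
    B_hat = np.asarray(B_hat, dtype=float)
    B_true = np.asarray(B_true, dtype=float)
    if B_hat.shape != B_true.shape:
        raise ValueError("B_hat and B_true must have the same shape")
    truth = (B_true != 0).ravel().astype(int)
    if truth.all() or not truth.any():
        raise ValueError("true support is degenerate (all zero or all nonzero)")
    return float(roc_auc_score(truth, np.abs(B_hat).ravel()))


def default_lambda_grid(ds: GroupedDataset, num: int = 20, ratio: float = 1e-3):
    """Log-spaced l1 weights from the null-solution threshold downward."""
    lmax = lambda_max(ds)
    return np.geomspace(lmax, lmax * ratio, num)


def default_gamma_grid(num: int = 8, lo: float = 1e-3, hi: float = 10.0):
    """``{0}`` plus ``num`` log-spaced fusion weights in ``[lo, hi]``."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, num)])


@dataclass
class CVResult:
    """Cross-validation table over a ``(lambda, gamma)`` grid."""

    lambdas: np.ndarray  # descending
    gammas: np.ndarray
    mean_rmse: np.ndarray  # len(lambdas) x len(gammas)
    sd_rmse: np.ndarray
    selected: tuple  # (lambda, gamma)
    fold_ids: np.ndarray
    seed: int
    penalty: str
    refit: FitResult | None = None
    tau: np.ndarray | None = field(default=None, repr=False)

    @property
    def selected_lambda(self) -> float:
        return self.selected[0]

    @property
    def selected_gamma(self) -> float:
        return self.selected[1]


def _fit_separable_lasso(ds, lam, warm=None, tol=1e-8):
    """Independent per-subgroup classical lasso (gamma = 0 / K = 1 path).

    The per-subgroup criterion ``(1/n_k)||y_k - X_k b||^2 + lam ||b||_1``
    matches scikit-learn's lasso at ``alpha = lam / 2``.
    """
    B = np.zeros((ds.p, ds.K))
    for k in range(ds.K):
        model = Lasso(
            alpha=max(lam, 1e-12) / 2.0,
            fit_intercept=False,
            tol=tol,
            max_iter=50_000,
            warm_start=warm is not None,
        )
        if warm is not None:
            model.coef_ = warm[:, k].copy()
            model.intercept_ = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(ds.X[k], ds.y[k])
        B[:, k] = model.coef_
    return B


def _fit_grid(ds, lambdas, gammas, tau, penalty, l1_epsilon=1e-3, tol=1e-7):
    """Fit every grid cell on ``ds``, warm-starting along descending lambda.

    Yields ``(i, j, B)`` with ``B`` the coefficient matrix.  ``tol`` is the
    per-fit solver tolerance; CV scoring tolerates a looser value than a
    final refit.
    """
    for j, gamma in enumerate(gammas):
        warm = None
        use_separable = penalty == "l2" and (gamma == 0.0 or ds.K == 1)
        prob = None
        if penalty == "l2" and not use_separable:
            spec0 = FusionSpec(lam=float(lambdas[0]), gamma=float(gamma), tau=tau,
                               mode="user-supplied" if tau is not None else "unweighted")
            prob = build_augmented(ds, spec0)
        for i, lam in enumerate(lambdas):
            spec = FusionSpec(lam=float(lam), gamma=float(gamma), tau=tau,
                              mode="user-supplied" if tau is not None else "unweighted")
            if use_separable:
                B = _fit_separable_lasso(ds, lam, warm, tol=tol)
            elif penalty == "l2":
                prob.spec = spec
                B = fit_l2_augmented(ds, spec, B_init=warm, problem=prob, tol=tol).B
            elif penalty == "l1":
                B = fit_l1_proximal(ds, spec, epsilon=l1_epsilon, B_init=warm).B
            else:
                raise ValueError(f"unknown penalty {penalty!r}")
            warm = B
            yield i, j, B


def cross_validate(
    ds: GroupedDataset,
    penalty: str = "l2",
    lambdas=None,
    gammas=None,
    tau: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    l1_epsilon: float = 1e-3,
    refit: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation over a ``(lambda, gamma)`` grid.

    Folds are stratified by subgroup so every training fold retains all K
    subgroups.  For each cell the model is fit on the training folds
    (warm-started along descending lambda within each gamma) and scored by
    held-out weighted RMSE; the cell minimizing the mean held-out error is
    selected and, by default, refit on the full dataset.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if (ds.n_k < n_folds).any():
        small = [ds.group_names[k] for k in np.flatnonzero(ds.n_k < n_folds)]
        raise ValueError(f"subgroup(s) {small} have fewer samples than folds")
    lambdas = np.sort(np.atleast_1d(
        default_lambda_grid(ds) if lambdas is None else np.asarray(lambdas, float)
    ))[::-1]
    gammas = np.atleast_1d(
        default_gamma_grid() if gammas is None else np.asarray(gammas, float)
    )

    X, y, labels = ds.to_arrays(raw=True)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_ids = np.empty(len(y), dtype=int)
    scores = np.zeros((n_folds, len(lambdas), len(gammas)))
    for f, (tr, te) in enumerate(skf.split(X, labels)):
        fold_ids[te] = f
        train = standardize_subgroups(split_by_group(X[tr], y[tr], labels[tr],
                                                     ds.feature_names))
        for i, j, B in _fit_grid(train, lambdas, gammas, tau, penalty, l1_epsilon):
            pred = predict(train, B, X[te], labels[te])
            scores[f, i, j] = weighted_rmse(pred, y[te], labels[te])

    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1) if n_folds > 1 else np.zeros_like(mean)
    i_best, j_best = np.unravel_index(np.argmin(mean), mean.shape)
    selected = (float(lambdas[i_best]), float(gammas[j_best]))

    refit_result = None
    if refit:
        spec = FusionSpec(lam=selected[0], gamma=selected[1], tau=tau,
                          mode="user-supplied" if tau is not None else "unweighted")
        if penalty == "l1":
            refit_result = fit_l1_proximal(ds, spec, epsilon=l1_epsilon)
        elif spec.gamma == 0.0 or ds.K == 1:
            B = _fit_separable_lasso(ds, spec.lam)
            refit_result = FitResult(
                B=B, objective_trace=np.empty(0), n_iter=0, converged=True,
                solver="l2-separable", spec=spec,
                group_names=list(ds.group_names),
                feature_names=list(ds.feature_names),
            )
        else:
            refit_result = fit_l2_augmented(ds, spec)
    return CVResult(
        lambdas=lambdas, gammas=gammas, mean_rmse=mean, sd_rmse=sd,
        selected=selected, fold_ids=fold_ids, seed=seed, penalty=penalty,
        refit=refit_result, tau=tau,
    )


def pool_dataset(ds: GroupedDataset) -> GroupedDataset:
    """Merge all subgroups into a single standardized group ("pooled")."""
    X, y, _ = ds.to_arrays(raw=True)
    pooled = split_by_group(X, y, np.repeat("pooled", len(y)), ds.feature_names)
    return standardize_subgroups(pooled)


def fit_baselines(
    ds: GroupedDataset, lambdas=None, n_folds: int = 10, seed: int = 0
) -> tuple[CVResult, CVResult]:
    """Pooled and subgroup-wise classical-lasso baselines, each CV-tuned.

    Pooled fits one lasso on all samples merged (the K = 1 special case);
    subgroup-wise fits an independent lasso per subgroup (the gamma = 0
    path).  Both select lambda by the same stratified CV as the joint fit.
    """
    pooled_ds = pool_dataset(ds)
    pooled = cross_validate(
        pooled_ds,
        lambdas=default_lambda_grid(pooled_ds) if lambdas is None else lambdas,
        gammas=[0.0], n_folds=n_folds, seed=seed,
    )
    subgroup = cross_validate(
        ds,
        lambdas=default_lambda_grid(ds) if lambdas is None else lambdas,
        gammas=[0.0], n_folds=n_folds, seed=seed,
    )
    return pooled, subgroup


def benchmark_replicate(
    design,
    seed: int,
    n_test: int = 500,
    n_lambdas: int = 15,
    gammas=None,
    n_folds: int = 5,
) -> dict:
    """One simulation replicate: joint lasso vs pooled and subgroup-wise.

    Simulates a training study from ``design``, tunes each method by CV,
    and scores weighted RMSE on an independently drawn test set from the
    same truth plus support-recovery AUROC against the true coefficients.
    """
    from .simulate import simulate_dataset, simulate_from_truth

    ds, truth = simulate_dataset(design, seed)
    test = simulate_from_truth(truth, n_test, seed + 2_000_003)
    X_te, y_te, lab_te = test.to_arrays(raw=True)

    lambdas = default_lambda_grid(ds, num=n_lambdas)
    if gammas is None:
        gammas = default_gamma_grid(num=5, lo=1e-2, hi=10.0)
    joint = cross_validate(ds, lambdas=lambdas, gammas=gammas,
                           n_folds=n_folds, seed=seed)
    pooled, subgroup = fit_baselines(ds, n_folds=n_folds, seed=seed)

    pred_joint = predict(ds, joint.refit.B, X_te, lab_te)
    pred_sub = predict(ds, subgroup.refit.B, X_te, lab_te)
    pooled_ds = pool_dataset(ds)
    pred_pool = predict(pooled_ds, pooled.refit.B, X_te,
                        np.repeat("pooled", len(y_te)))
    B_pool_full = np.tile(pooled.refit.B, (1, ds.K))
    return {
        "joint_rmse": weighted_rmse(pred_joint, y_te, lab_te),
        "pooled_rmse": weighted_rmse(pred_pool, y_te, lab_te),
        "subgroup_rmse": weighted_rmse(pred_sub, y_te, lab_te),
        "joint_auroc": support_auroc(joint.refit.B, truth.B),
        "pooled_auroc": support_auroc(B_pool_full, truth.B),
        "subgroup_auroc": support_auroc(subgroup.refit.B, truth.B),
        "selected_lambda": joint.selected_lambda,
        "selected_gamma": joint.selected_gamma,
    }
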