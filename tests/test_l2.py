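import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from jointlasso import (
    FusionSpec,
    build_augmented,
    build_fusion_rows,
    coordinate_update,
    fit_l2_augmented,
    fit_l2_cd,
    lambda_max,
    objective_l2,
)
from jointlasso.data import GroupedDataset
from jointlasso.l2 import kkt_violation
from conftest import make_grouped
from oracles import sklearn_lasso


class TestObjective:
    def test_null_coefficients_leave_only_loss(self, small_ds, spec):
        expected = sum(
            small_ds.y[k] @ small_ds.y[k] / small_ds.n_k[k]
            for k in range(small_ds.K)
        )
        B0 = np.zeros((small_ds.p, small_ds.K))
        assert objective_l2(B0, small_ds, spec) == pytest.approx(expected)

    def test_single_group_is_classical_lasso_objective(self):
        ds = make_grouped(seed=2, p=4, K=1, n_k=30)
        B = np.random.default_rng(0).standard_normal((4, 1))
        spec = FusionSpec(lam=0.3, gamma=0.7)  # gamma irrelevant at K=1
        r = ds.y[0] - ds.X[0] @ B[:, 0]
        expected = r @ r / 30 + 0.3 * np.abs(B).sum()
        assert objective_l2(B, ds, spec) == pytest.approx(expected)

    def test_equal_columns_zero_fusion(self, small_ds):
        b = np.random.default_rng(1).standard_normal(small_ds.p)
        B = np.tile(b[:, None], (1, small_ds.K))
        with_fusion = objective_l2(B, small_ds, FusionSpec(lam=0.1, gamma=5.0))
        without = objective_l2(B, small_ds, FusionSpec(lam=0.1, gamma=0.0))
        assert with_fusion == pytest.approx(without)


class TestCoordinateUpdate:
    def test_no_penalties_gives_univariate_ls(self, small_ds):
        spec = FusionSpec(lam=0.0, gamma=0.0)
        B = np.zeros((small_ds.p, small_ds.K))
        x = small_ds.X[0][:, 2]
        expected = x @ small_ds.y[0] / (x @ x)
        assert coordinate_update(2, 0, B, small_ds, spec) == pytest.approx(expected)

    def test_zero_column_pure_fusion_pull(self):
        # a feature with no variance contribution is pulled to the
        # tau-weighted mean of the other subgroups' coefficients
        rng = np.random.default_rng(7)
        Xs = [rng.standard_normal((6, 3)) for _ in range(3)]
        Xs[0][:, 1] = 0.0
        ds = GroupedDataset(
            X=Xs, y=[rng.standard_normal(6) for _ in range(3)],
            group_names=["a", "b", "c"], feature_names=["x0", "x1", "x2"],
            standardized=True,
        )
        tau = np.array([[0, 0.5, 1.0], [0.5, 0, 0], [1.0, 0, 0]])
        spec = FusionSpec(lam=0.0, gamma=2.0, tau=tau, mode="user-supplied")
        B = np.zeros((3, 3))
        B[1, 1], B[1, 2] = 4.0, 1.0
        expected = (0.5 * 4.0 + 1.0 * 1.0) / 1.5
        assert coordinate_update(1, 0, B, ds, spec) == pytest.approx(expected)

    def test_matches_scalar_convex_minimization(self, two_group_ds):
        spec = FusionSpec(lam=0.2, gamma=0.5)
        rng = np.random.default_rng(8)
        B = rng.standard_normal((two_group_ds.p, 2))
        for j, k in [(0, 0), (3, 1), (4, 0)]:
            def scalar_obj(b):
                Bt = B.copy()
                Bt[j, k] = b
                return objective_l2(Bt, two_group_ds, spec)

            res = minimize_scalar(scalar_obj, bounds=(-10, 10), method="bounded",
                                  options={"xatol": 1e-10})
            assert coordinate_update(j, k, B, two_group_ds, spec) == pytest.approx(
                res.x, abs=1e-6
            )


class TestCoordinateDescent:
    def test_large_lambda_gives_null_solution(self, small_ds):
        spec = FusionSpec(lam=lambda_max(small_ds) * 1.01, gamma=0.3)
        fit = fit_l2_cd(small_ds, spec, tol=1e-8)
        np.testing.assert_array_equal(fit.B, 0.0)

    def test_gamma_zero_matches_reference_lasso(self, small_ds):
        spec = FusionSpec(lam=0.25, gamma=0.0)
        fit = fit_l2_cd(small_ds, spec, tol=1e-10, max_iter=5000)
        for k in range(small_ds.K):
            ref = sklearn_lasso(small_ds.X[k], small_ds.y[k], 0.25)
            np.testing.assert_allclose(fit.B[:, k], ref, atol=1e-4)

    def test_identical_subgroups_yield_identical_columns(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        ds = GroupedDataset(
            X=[X.copy(), X.copy()], y=[y.copy(), y.copy()],
            group_names=["a", "b"], feature_names=[f"x{i}" for i in range(6)],
            standardized=True,
        )
        fit = fit_l2_cd(ds, FusionSpec(lam=0.1, gamma=0.8), tol=1e-9, max_iter=3000)
        np.testing.assert_allclose(fit.B[:, 0], fit.B[:, 1], atol=1e-6)

    def test_objective_trace_non_increasing(self, small_ds, spec):
        fit = fit_l2_cd(small_ds, spec, tol=1e-9, max_iter=2000)
        assert np.all(np.diff(fit.objective_trace) <= 1e-12)
        assert fit.converged

    def test_kkt_conditions_hold_at_convergence(self, small_ds, spec):
        fit = fit_l2_cd(small_ds, spec, tol=1e-9, max_iter=3000)
        assert kkt_violation(fit.B, small_ds, spec) < 1e-6


class TestFusionRows:
    def test_dimensions_and_block_count(self):
        spec = FusionSpec(lam=0.1, gamma=0.5)
        G = build_fusion_rows(2, 3, spec).toarray()
        assert G.shape == (6, 6)
        # three pair blocks of two rows each, each row two nonzeros
        assert (np.count_nonzero(G, axis=1) == 2).all()

    def test_zero_weight_pair_gives_zero_rows(self):
        tau = np.array([[0, 1.0, 0.0], [1.0, 0, 1.0], [0.0, 1.0, 0]])
        spec = FusionSpec(lam=0.1, gamma=0.5, tau=tau, mode="user-supplied")
        G = build_fusion_rows(2, 3, spec).toarray()
        # pair (0,2) is the second block (rows 2,3)
        assert np.all(G[2:4] == 0)

    def test_equal_columns_in_null_space(self):
        spec = FusionSpec(lam=0.1, gamma=0.7)
        p, K = 4, 3
        G = build_fusion_rows(p, K, spec)
        b = np.tile(np.random.default_rng(0).standard_normal(p), K)
        np.testing.assert_allclose(G @ b, 0, atol=1e-12)

    def test_quadratic_form_reproduces_fusion_term(self):
        rng = np.random.default_rng(3)
        p, K = 3, 4
        tau = rng.random((K, K))
        tau = (tau + tau.T) / 2
        np.fill_diagonal(tau, 0)
        spec = FusionSpec(lam=0.0, gamma=0.9, tau=tau, mode="user-supplied")
        B = rng.standard_normal((p, K))
        G = build_fusion_rows(p, K, spec)
        direct = sum(
            0.9 * tau[k, k2] * np.sum((B[:, k] - B[:, k2]) ** 2)
            for k in range(K) for k2 in range(k + 1, K)
        )
        val = G @ B.T.ravel()
        assert val @ val == pytest.approx(direct, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            build_fusion_rows(3, 1, FusionSpec(lam=0.1, gamma=0.5))


class TestAugmented:
    def test_dimensions(self):
        ds = make_grouped(seed=4, p=3, K=2, n_k=4)
        prob = build_augmented(ds, FusionSpec(lam=0.1, gamma=0.5))
        assert prob.shape == (8 + 3, 6)  # n + p*K(K-1)/2 rows, pK cols
        assert np.all(prob.y_aug[8:] == 0)

    def test_gamma_zero_reduces_to_independent_lassos(self, small_ds):
        spec = FusionSpec(lam=0.3, gamma=0.0)
        fit = fit_l2_augmented(small_ds, spec)
        for k in range(small_ds.K):
            ref = sklearn_lasso(small_ds.X[k], small_ds.y[k], 0.3)
            np.testing.assert_allclose(fit.B[:, k], ref, atol=1e-4)

    def test_unpenalized_fit_is_least_squares(self):
        ds = make_grouped(seed=5, p=3, K=2, n_k=12)
        fit = fit_l2_augmented(ds, FusionSpec(lam=0.0, gamma=0.0))
        for k in range(2):
            ols = np.linalg.lstsq(ds.X[k], ds.y[k], rcond=None)[0]
            np.testing.assert_allclose(fit.B[:, k], ols, atol=1e-6)

    def test_agrees_with_coordinate_descent(self):
        ds = make_grouped(seed=6, p=10, K=3, n_k=20)
        spec = FusionSpec(lam=0.15, gamma=0.4)
        cd = fit_l2_cd(ds, spec, tol=1e-9, max_iter=5000)
        aug = fit_l2_augmented(ds, spec)
        assert np.abs(cd.B - aug.B).max() < 1e-4

    def test_fusion_dominant_limit_coalesces_columns(self, small_ds):
        fit = fit_l2_augmented(small_ds, FusionSpec(lam=0.1, gamma=1e4))
        spread = np.abs(fit.B[:, :, None] - fit.B[:, None, :]).max()
        assert spread < 1e-3


def test_fusion_strength_monotonically_shrinks_column_spread(small_ds):
    spreads = []
    for gamma in [0.0, 0.1, 1.0, 10.0, 100.0]:
        fit = fit_l2_cd(small_ds, FusionSpec(lam=0.1, gamma=gamma),
                        tol=1e-8, max_iter=3000)
        spreads.append(np.abs(fit.B[:, :, None] - fit.B[:, None, :]).max())
    assert all(a >= b - 1e-8 for a, b in zip(spreads, spreads[1:]))
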