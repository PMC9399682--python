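"""Solver contract: objective components, prox exactness, global optimality."""

import numpy as np
import pytest

from adcascade.tglasso import (
    LongitudinalDesign,
    RegularizationParams,
    fit,
    group_penalty,
    lambda_zero_threshold,
    loss,
    objective,
    smooth_penalty,
    standardize_design,
    tv1d_prox,
)

from _oracles import random_design, smoothed_min_objective, tv_prox_oracle


def naive_objective(design, W, params):
    """Direct double-loop evaluation of every term, no vectorisation."""
    total = 0.0
    for j in range(design.T):
        for i in range(design.X[j].shape[0]):
            r = design.y[j][i] - float(design.X[j][i] @ W[:, j])
            total += 0.5 * r * r
    for row in W:
        total += params.lambda1 * float(np.sqrt(np.sum(row**2)))
    for j in range(design.T - 1):
        for i in range(design.d):
            total += params.lambda2 * abs(W[i, j] - W[i, j + 1])
        dv = design.X[j] @ W[:, j] - design.X[j + 1] @ W[:, j + 1]
        total += params.lambda3 * float(dv @ dv)
    return total


class TestObjectiveComponents:
    def test_loss_of_exact_solution_is_zero(self, rng):
        X = [rng.normal(size=(3, 3)) + 3 * np.eye(3) for _ in range(2)]
        W = rng.normal(size=(3, 2))
        y = [X[j] @ W[:, j] for j in range(2)]
        assert loss(LongitudinalDesign(X, y), W) == pytest.approx(0.0, abs=1e-18)

    def test_loss_single_point(self):
        design = LongitudinalDesign([np.array([[1.0]])], [np.array([2.0])])
        assert loss(design, np.array([[0.0]])) == 2.0

    def test_group_penalty_345_row(self):
        assert group_penalty(np.array([[3.0, 4.0]]), 1.0) == 5.0
        assert group_penalty(np.zeros((4, 3)), 2.0) == 0.0

    def test_smooth_penalty_equal_columns_vanishes(self, rng):
        X0 = rng.normal(size=(5, 3))
        design = LongitudinalDesign([X0, X0], [rng.normal(size=5)] * 2)
        W = np.tile(rng.normal(size=(3, 1)), (1, 2))
        assert smooth_penalty(design, W, 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_smooth_penalty_unit_swap(self, rng):
        design = random_design(rng, d=1, T=2, n=3)
        W = np.array([[1.0, 0.0]])
        # lambda3 = 0 isolates the fused term: |1-0| summed over the single row
        assert smooth_penalty(design, W, 1.0, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_naive_summation(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng)
        W = rng.normal(size=(design.d, design.T))
        params = RegularizationParams(*rng.uniform(0.0, 2.0, 3))
        assert objective(design, W, params) == pytest.approx(
            naive_objective(design, W, params), rel=1e-12
        )

    def test_objective_reduces_to_loss_without_penalties(self, rng):
        design = random_design(rng)
        W = rng.normal(size=(design.d, design.T))
        params = RegularizationParams(0.0, 0.0, 0.0)
        assert objective(design, W, params) == pytest.approx(loss(design, W), rel=1e-14)

    def test_objective_at_zero_is_half_response_energy(self, rng):
        design = random_design(rng)
        expected = 0.5 * sum(float(yj @ yj) for yj in design.y)
        params = RegularizationParams(0.7, 0.3, 0.2)
        assert objective(design, np.zeros((design.d, design.T)), params) == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            RegularizationParams(-0.1, 0.0, 0.0)
        with pytest.raises(ValueError):
            group_penalty(np.ones((2, 2)), -1.0)


class TestTVProx:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dual_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        v = rng.normal(0, rng.choice([0.1, 1, 10]), n)
        lam = float(rng.choice([0.01, 0.1, 0.5, 1.0, 5.0]))
        x = tv1d_prox(v, lam)
        xo = tv_prox_oracle(v, lam)

        def J(z):
            return 0.5 * np.sum((z - v) ** 2) + lam * np.sum(np.abs(np.diff(z)))

        # exact solver must not be beaten by the iterative dual oracle
        assert J(x) <= J(xo) + 1e-10
        assert np.allclose(x, xo, atol=1e-6)

    def test_large_penalty_pools_to_mean(self, rng):
        v = rng.normal(size=6)
        x = tv1d_prox(v, 1e6)
        assert np.allclose(x, v.mean(), atol=1e-9)

    def test_zero_penalty_identity(self, rng):
        v = rng.normal(size=5)
        assert np.array_equal(tv1d_prox(v, 0.0), v)


class TestFit:
    @pytest.mark.parametrize("seed", range(6))
    def test_attains_convex_oracle_optimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        design = random_design(rng)
        params = RegularizationParams(*rng.uniform(0.01, 1.0, 3))
        report = fit(design, params, max_iter=5000, tol=1e-10)
        oracle = smoothed_min_objective(design, params)
        achieved = report.objective_trace[-1]
        assert achieved <= oracle + 1e-6 * max(abs(oracle), 1.0)

    def test_unpenalized_limit_matches_least_squares(self, rng):
        d, T, n = 4, 3, 4
        X = [rng.normal(size=(n, d)) + np.eye(n, d) for _ in range(T)]
        y = [rng.normal(size=n) for _ in range(T)]
        design = LongitudinalDesign(X, y)
        report = fit(design, RegularizationParams(0, 0, 0), tol=1e-12)
        for j in range(T):
            wls = np.linalg.lstsq(X[j], y[j], rcond=None)[0]
            assert np.allclose(report.W_hat[:, j], wls, atol=1e-6)

    def test_above_zero_threshold_gives_exact_zero(self, rng):
        design = random_design(rng, d=5, T=3, n=8)
        lam_max = lambda_zero_threshold(design)
        report = fit(design, RegularizationParams(lam_max * 1.001, 0.0, 0.0))
        assert np.all(report.W_hat == 0.0)
        below = fit(design, RegularizationParams(lam_max * 0.9, 0.0, 0.0))
        assert np.any(below.W_hat != 0.0)

    def test_objective_trace_monotone(self, rng):
        design = random_design(rng, d=6, T=3, n=10)
        report = fit(design, RegularizationParams(0.5, 0.2, 0.1))
        assert np.all(np.diff(report.objective_trace) <= 1e-10)

    def test_row_sparsity_monotone_in_lambda1(self):
        rng = np.random.default_rng(7)
        design = random_design(rng, d=8, T=3, n=20)
        lam_max = lambda_zero_threshold(design)
        n_active = []
        for frac in (0.01, 0.05, 0.2, 0.5, 0.9, 1.1):
            rep = fit(design, RegularizationParams(frac * lam_max, 0.0, 0.0), tol=1e-10)
            n_active.append(int(np.sum(np.linalg.norm(rep.W_hat, axis=1) > 1e-8)))
        assert n_active == sorted(n_active, reverse=True)
        assert n_active[-1] == 0

    def test_fusion_limit_pools_time_points(self, rng):
        d, T, n = 3, 3, 12
        X = [rng.normal(size=(n, d)) for _ in range(T)]
        y = [rng.normal(size=n) for _ in range(T)]
        design = LongitudinalDesign(X, y)
        rep = fit(design, RegularizationParams(0.0, 1e6, 0.0), max_iter=8000, tol=1e-12)
        W = rep.W_hat
        assert np.max(np.abs(W - W[:, [0]])) <= 1e-4
        # pooled single-weight regression: (sum X_j'X_j) w = sum X_j'y_j
        A = sum(Xj.T @ Xj for Xj in X)
        b = sum(Xj.T @ yj for Xj, yj in zip(X, y))
        pooled = np.linalg.solve(A, b)
        assert np.allclose(W[:, 0], pooled, atol=1e-3)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        design = random_design(rng, d=6, T=2, n=15)
        params = RegularizationParams(0.8, 0.3, 0.1)
        rep = fit(design, params, tol=1e-10)
        perm = rng.permutation(design.d)
        design_p = LongitudinalDesign([Xj[:, perm] for Xj in design.X], design.y)
        rep_p = fit(design_p, params, tol=1e-10)
        assert np.allclose(rep_p.W_hat, rep.W_hat[perm], atol=1e-6)

    def test_nan_input_rejected(self, rng):
        design = random_design(rng, d=3, T=2, n=5)
        design.X[0][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit(design, RegularizationParams())

    def test_misaligned_rows_rejected_when_output_smoothness_active(self, rng):
        X = [rng.normal(size=(5, 3)), rng.normal(size=(6, 3))]
        y = [rng.normal(size=5), rng.normal(size=6)]
        design = LongitudinalDesign(X, y)
        with pytest.raises(ValueError, match="row-aligned"):
            fit(design, RegularizationParams(0.1, 0.1, 0.1))
        # without lambda3 the unequal design is legal
        rep = fit(design, RegularizationParams(0.1, 0.1, 0.0))
        assert rep.W_hat.shape == (3, 2)

    def test_nonconvergence_reported_not_raised(self, rng):
        design = random_design(rng, d=6, T=3, n=10)
        rep = fit(design, RegularizationParams(0.5, 0.2, 0.1), max_iter=3)
        assert rep.converged is False
        assert rep.iterations == 3


class TestZeroThreshold:
    def test_zero_response_gives_zero(self, rng):
        X = [rng.normal(size=(4, 3)) for _ in range(2)]
        y = [np.zeros(4), np.zeros(4)]
        assert lambda_zero_threshold(LongitudinalDesign(X, y)) == 0.0

    def test_identity_design_single_visit(self):
        design = LongitudinalDesign([np.eye(2)], [np.array([3.0, 4.0])])
        assert lambda_zero_threshold(design) == 4.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_subgradient_condition(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng)
        B = np.column_stack([design.X[j].T @ design.y[j] for j in range(design.T)])
        expected = max(np.sqrt(np.sum(row**2)) for row in B)
        assert lambda_zero_threshold(design) == pytest.approx(expected, rel=1e-10)


def test_standardize_design_zscores_and_centers(rng):
    design = random_design(rng, d=4, T=2, n=30)
    std, stats = standardize_design(design)
    for j in range(2):
        assert np.allclose(std.X[j].mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(std.X[j].std(axis=0), 1.0, atol=1e-12)
        assert std.y[j].mean() == pytest.approx(0.0, abs=1e-12)
    assert "per_visit" in stats
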