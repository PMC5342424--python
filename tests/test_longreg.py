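"""Longitudinal sparse regression: objective, reweighting, solver, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radiogen_psp as r
from radiogen_psp.containers import unfold_coefficients


def random_instance(rng, n=15, d=6, c=4, T=3, noise=0.3):
    X = rng.standard_normal((n, d, T))
    W = rng.standard_normal((d, c, T))
    Y = sum(X[:, :, t] @ W[:, :, t] for t in range(T)) / T
    Y = Y + noise * rng.standard_normal((n, c))
    return X, Y


def objective_oracle(X, Y, W, theta1, theta2):
    """Direct re-evaluation with explicit loops and an explicit SVD."""
    n, d, T = X.shape
    rss = 0.0
    for t in range(T):
        rss += np.linalg.norm(X[:, :, t] @ W[:, :, t] - Y, "fro") ** 2
    Wbar = W.mean(axis=2)
    group = 0.0
    for k in range(d):
        dev = 0.0
        for t in range(T):
            dev += np.linalg.norm(W[k, :, t] - Wbar[k, :]) ** 2
        group += np.sqrt(dev)
    trace = np.linalg.svd(unfold_coefficients(W), compute_uv=False).sum()
    return rss + theta1 * group + theta2 * trace


class TestObjective:
    def test_zero_coefficients_leave_only_residual(self, rng):
        X, Y = random_instance(rng)
        W = np.zeros((6, 4, 3))
        conf = r.RegressionConfig(theta1=2.0, theta2=5.0)
        assert r.objective(X, Y, W, conf) == pytest.approx(3 * np.linalg.norm(Y) ** 2)

    def test_no_penalties_reduces_to_rss(self, rng):
        X, Y = random_instance(rng)
        W = rng.standard_normal((6, 4, 3))
        conf = r.RegressionConfig(theta1=0.0, theta2=0.0)
        rss = sum(np.linalg.norm(X[:, :, t] @ W[:, :, t] - Y) ** 2 for t in range(3))
        assert r.objective(X, Y, W, conf) == pytest.approx(rss)

    def test_random_instance_matches_direct_reevaluation(self, rng):
        X = rng.standard_normal((5, 4, 2))
        Y = rng.standard_normal((5, 3))
        W = rng.standard_normal((4, 3, 2))
        conf = r.RegressionConfig(theta1=1.7, theta2=0.9)
        assert r.objective(X, Y, W, conf) == pytest.approx(
            objective_oracle(X, Y, W, 1.7, 0.9), rel=1e-12
        )

    def test_dimension_mismatch_names_axis(self, rng):
        X, Y = random_instance(rng)
        with pytest.raises(r.DimensionError, match="W shape"):
            r.objective(X, Y, np.zeros((6, 5, 3)), r.RegressionConfig())


class TestReweighting:
    def test_time_constant_w_gives_constant_diagonal(self, rng):
        eps = 1e-8
        Wt = rng.standard_normal((5, 3))
        W = np.repeat(Wt[:, :, None], 4, axis=2)
        state = r.update_reweighting(W, eps)
        np.testing.assert_allclose(state.D, 1.0 / (2.0 * np.sqrt(eps)))

    def test_zero_w_state(self):
        eps = 1e-8
        state = r.update_reweighting(np.zeros((4, 2, 3)), eps)
        assert not state.Dbar.any()
        np.testing.assert_allclose(state.Ddbar, 0.5 / np.sqrt(eps) * np.eye(4))

    def test_trace_reweighting_matches_matrix_function_oracle(self, rng):
        W = rng.standard_normal((6, 4, 3))
        eps = 1e-8
        state = r.update_reweighting(W, eps)
        M = unfold_coefficients(W)
        target = np.linalg.inv(M @ M.T + eps * np.eye(6))
        np.testing.assert_allclose(4 * state.Ddbar @ state.Ddbar, target, atol=1e-8)
        assert np.allclose(state.Ddbar, state.Ddbar.T)
        assert np.linalg.eigvalsh(state.Ddbar).min() > 0

    def test_nonfinite_w_rejected(self):
        W = np.zeros((2, 2, 2))
        W[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            r.update_reweighting(W)


class TestFit:
    def test_ols_limit_matches_normal_equations(self, rng):
        X = rng.standard_normal((50, 5, 1))
        W_true = rng.standard_normal((5, 4, 1))
        Y = X[:, :, 0] @ W_true[:, :, 0] + 0.1 * rng.standard_normal((50, 4))
        conf = r.RegressionConfig(
            theta1=0.0, theta2=0.0, max_iter=3, tol=None, ridge_init=0.0,
            standardize_y=False,
        )
        W_fit, _ = r.fit(X, Y, conf)
        W_ols = np.linalg.solve(X[:, :, 0].T @ X[:, :, 0], X[:, :, 0].T @ Y)
        assert np.abs(W_fit.values[:, :, 0] - W_ols).max() < 1e-6

    def test_huge_smoothness_forces_time_constant_coefficients(self, rng):
        X, Y = random_instance(rng, n=20, d=8, c=5, T=3)
        conf = r.RegressionConfig(
            theta1=1e6, theta2=0.0, max_iter=500, tol=None, standardize_y=False
        )
        W_fit, _ = r.fit(X, Y, conf)
        Wbar = W_fit.values.mean(axis=2, keepdims=True)
        assert np.abs(W_fit.values - Wbar).max() < 1e-3

    def test_objective_trace_non_increasing(self, rng):
        X, Y = random_instance(rng, n=18, d=7, c=5, T=3)
        for theta in (0.1, 1.0, 10.0):
            conf = r.RegressionConfig(
                theta1=theta, theta2=theta, max_iter=80, tol=None, standardize_y=False
            )
            _, state = r.fit(X, Y, conf)
            tr = np.asarray(state.objective_trace)
            rel_increase = np.diff(tr) / np.maximum(1.0, np.abs(tr[:-1]))
            assert rel_increase[1:].max() <= 1e-6

    def test_singular_unregularized_system_raises_advice(self, rng):
        X = rng.standard_normal((4, 8, 1))  # d > n: rank-deficient gram
        Y = rng.standard_normal((4, 3))
        conf = r.RegressionConfig(theta1=0.0, theta2=0.0, ridge_init=0.0, max_iter=5)
        with pytest.raises(r.SingularSystemError, match="ridge_init"):
            r.fit(X, Y, conf)

    def test_tolerance_stops_early(self, rng):
        X, Y = random_instance(rng)
        conf = r.RegressionConfig(theta1=1.0, theta2=1.0, max_iter=500, tol=1e-10)
        _, state = r.fit(X, Y, conf)
        assert state.converged
        assert state.n_iter < 500

    def test_temporal_variance_decreases_with_theta1(self, rng):
        X, Y = random_instance(rng, n=25, d=8, c=5, T=3)
        variances = []
        for theta1 in (0.1, 1.0, 10.0, 1000.0):
            conf = r.RegressionConfig(
                theta1=theta1, theta2=0.1, max_iter=300, tol=None, standardize_y=False
            )
            W_fit, _ = r.fit(X, Y, conf)
            Wbar = W_fit.values.mean(axis=2, keepdims=True)
            variances.append(float(((W_fit.values - Wbar) ** 2).sum()))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(variances, variances[1:]))

    def test_unfolded_rank_non_increasing_with_theta2(self, rng):
        X, Y = random_instance(rng, n=25, d=8, c=5, T=3)
        ranks = []
        for theta2 in (0.1, 1.0, 10.0, 100.0):
            conf = r.RegressionConfig(
                theta1=0.1, theta2=theta2, max_iter=300, tol=None, standardize_y=False
            )
            W_fit, _ = r.fit(X, Y, conf)
            sv = np.linalg.svd(W_fit.unfold(), compute_uv=False)
            ranks.append(int((sv > 1e-6 * sv[0]).sum()))
        assert all(b <= a for a, b in zip(ranks, ranks[1:]))

    def test_permuting_gene_columns_permutes_coefficients(self, rng):
        X, Y = random_instance(rng)
        perm = rng.permutation(Y.shape[1])
        conf = r.RegressionConfig(theta1=1.0, theta2=1.0, max_iter=50, tol=None)
        W_a, _ = r.fit(X, Y, conf)
        W_b, _ = r.fit(X, Y[:, perm], conf)
        np.testing.assert_allclose(W_b.values, W_a.values[:, perm, :], atol=1e-10)

    def test_snapshots_equal_independent_fixed_count_runs(self, rng):
        X, Y = random_instance(rng)
        conf = r.RegressionConfig(theta1=2.0, theta2=2.0, max_iter=40, tol=None)
        _, state = r.fit(X, Y, conf, snapshot_iters=[10, 25, 40])
        for iters in (10, 25, 40):
            conf_i = r.RegressionConfig(theta1=2.0, theta2=2.0, max_iter=iters, tol=None)
            W_i, _ = r.fit(X, Y, conf_i)
            np.testing.assert_array_equal(state.snapshots[iters], W_i.values)


class TestWeights:
    def test_zero_tensor_gives_zero_weights(self):
        wmap = r.overall_weights(np.zeros((4, 3, 2)))
        assert not wmap.weights.any()
        assert not wmap.avg_weight.any()

    def test_single_negative_entry_uses_absolute_value(self):
        W = np.zeros((6, 4, 4))
        W[5, 3, 2] = -2.0
        wmap = r.overall_weights(W)
        assert wmap.weights[2, 3] == 2.0
        assert wmap.avg_weight[3] == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_weights_match_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((5, 4, 3))
        wmap = r.overall_weights(W)
        for t in range(3):
            for j in range(4):
                expected = sum(abs(W[i, j, t]) for i in range(5))
                assert wmap.weights[t, j] == pytest.approx(expected, rel=1e-12)

    def test_top_genes_ranking_and_bounds(self):
        W = np.zeros((2, 3, 1))
        W[:, 0, 0] = [1.5, 1.5]  # weight 3
        W[:, 1, 0] = [0.5, 0.5]  # weight 1
        W[:, 2, 0] = [1.0, 1.0]  # weight 2
        wmap = r.overall_weights(W)
        assert list(r.top_genes(wmap, 2)) == [0, 2]
        assert list(r.top_genes(wmap, 3)) == [0, 2, 1]
        with pytest.raises(ValueError, match="exceeds"):
            r.top_genes(wmap, 4)

    def test_planted_genes_dominate_weight_ranking(self):
        # support-recovery: fit on the generative scale; planted genes must
        # fill the top of the average-weight ranking at moderate noise
        recovered = []
        for seed in range(10):
            cohort = r.generate_dataset(r.small_profile(seed=seed))
            conf = r.RegressionConfig(
                theta1=1.0, theta2=1.0, max_iter=200, tol=None, standardize_y=False
            )
            W_fit, _ = r.fit(cohort.X, cohort.Y, conf)
            top = r.top_genes(r.overall_weights(W_fit), 5)
            recovered.append(np.isin(cohort.active_genes, top).mean())
        assert np.mean(recovered) >= 0.8
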