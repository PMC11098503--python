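"""Kernel ridge encoding: dof path, dual solver, scoring, significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from latentcoding.encoding import (
    assign_complexity,
    compare_encoders,
    critical_correlation,
    cv_select_lambda,
    effective_dof,
    fit_kernel_ridge,
    lambda_grid,
    predict,
    score_encoders,
    solve_lambda_for_dof,
)


class TestEffectiveDof:
    @pytest.mark.parametrize(
        "lam,s,expected",
        [
            (0.0, [3.0, 2.0, 1.0], 3.0),  # dof(0) = rank
            (1.0, [1.0, 1.0], 1.0),
            (4.0, [2.0], 0.5),
        ],
    )
    def test_closed_form_values(self, lam, s, expected):
        assert effective_dof(lam, np.array(s)) == pytest.approx(expected)

    def test_strictly_decreasing_and_convex_in_lambda(self, rng):
        s = rng.uniform(0.5, 5.0, size=12)
        lams = np.linspace(0.0, 50.0, 200)
        d = np.array([effective_dof(l, s) for l in lams])
        assert np.all(np.diff(d) < 0)
        assert np.all(np.diff(d, 2) > -1e-12)  # convex

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            effective_dof(-0.1, np.array([1.0]))


class TestSolveLambdaForDof:
    @pytest.mark.parametrize(
        "target,s,expected",
        [
            (1.0, [1.0, 1.0], 1.0),
            (2.0, [1.0, 1.0], 0.0),  # target = rank -> lam = 0
            (0.5, [2.0], 4.0),
        ],
    )
    def test_closed_form_inversions(self, target, s, expected):
        assert solve_lambda_for_dof(target, np.array(s)) == pytest.approx(
            expected, abs=1e-5
        )

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_identity_within_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.1, 10.0, size=rng.integers(2, 20))
        target = rng.uniform(0.5, len(s))
        lam = solve_lambda_for_dof(target, s, tol=1e-6)
        assert effective_dof(lam, s) == pytest.approx(target, abs=2e-6)

    def test_target_outside_range_raises(self):
        with pytest.raises(ValueError):
            solve_lambda_for_dof(0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            solve_lambda_for_dof(3.0, np.array([1.0, 1.0]))


class TestLambdaGrid:
    def test_two_point_grid_hits_dof_one_and_rank(self):
        s = np.array([1.0, 1.0, 1.0])
        grid = lambda_grid(s, m=2)
        assert grid[0] == pytest.approx(2.0, abs=1e-5)  # dof=1 for 3 unit sv
        assert grid[1] == 0.0  # dof=rank

    def test_grid_positive_except_at_full_dof_and_decreasing(self, rng):
        s = rng.uniform(0.5, 4.0, size=10)
        grid = lambda_grid(s, m=8)
        assert np.all(grid[:-1] > 0)
        assert grid[-1] == 0.0
        assert np.all(np.diff(grid) < 0)

    def test_round_trip_self_consistency(self, rng):
        s = rng.uniform(0.5, 4.0, size=9)
        m = 6
        grid = lambda_grid(s, m=m, tol=1e-8)
        targets = np.linspace(1.0, 9, m)
        recovered = [effective_dof(l, s) for l in grid]
        np.testing.assert_allclose(recovered, targets, atol=1e-6)

    def test_small_grid_raises(self):
        with pytest.raises(ValueError):
            lambda_grid(np.array([1.0]), m=1)


class TestFitKernelRidge:
    def test_identity_design_interpolates_at_lambda_zero(self):
        n = 5
        y = np.arange(n, dtype=float)[:, None]
        model = fit_kernel_ridge(np.eye(n), y, lam=0.0)
        np.testing.assert_allclose(predict(model, np.eye(n)), y, atol=1e-8)

    def test_huge_lambda_shrinks_to_training_mean(self, rng):
        x = rng.standard_normal((20, 4))
        y = rng.standard_normal((20, 2))
        model = fit_kernel_ridge(x, y, lam=1e12)
        pred = predict(model, rng.standard_normal((6, 4)))
        np.testing.assert_allclose(pred, np.tile(y.mean(0), (6, 1)), atol=1e-6)

    def test_dual_matches_primal_ridge_oracle(self, rng):
        """Dual (N x N) predictions equal primal (q x q) ridge."""
        n, q, lam = 6, 9, 0.7
        x = rng.standard_normal((n, q))
        y = rng.standard_normal((n, 1))
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        w_primal = np.linalg.solve(xc.T @ xc + lam * np.eye(q), xc.T @ yc)
        xs = rng.standard_normal((4, q))
        primal_pred = (xs - x.mean(0)) @ w_primal + y.mean(0)
        model = fit_kernel_ridge(x, y, lam=lam)
        np.testing.assert_allclose(predict(model, xs), primal_pred, atol=1e-8)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            fit_kernel_ridge(rng.standard_normal((4, 2)), np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            fit_kernel_ridge(rng.standard_normal((4, 2)), np.zeros(4), -1.0)


class TestCvSelectLambda:
    def test_single_value_grid_returns_it(self, rng):
        x = rng.standard_normal((20, 3))
        y = rng.standard_normal((20, 2))
        lam, _ = cv_select_lambda(x, y, np.array([2.5]), k=4)
        assert lam == 2.5

    def test_noiseless_linear_data_selects_smallest_lambda(self, rng):
        x = rng.standard_normal((60, 5))
        y = x @ rng.standard_normal((5, 3))
        grid = np.array([10.0, 1.0, 0.01])
        lam, mse = cv_select_lambda(x, y, grid, k=5, seed=0)
        assert lam == 0.01
        assert np.all(np.diff(mse) < 0)  # error falls with less shrinkage

    def test_exact_tie_breaks_to_smaller_lambda(self, rng):
        x = rng.standard_normal((16, 3))
        y = rng.standard_normal((16, 1))
        lam, _ = cv_select_lambda(x, y, np.array([3.0, 3.0]), k=4)
        assert lam == 3.0

    def test_too_many_folds_raise(self, rng):
        with pytest.raises(ValueError):
            cv_select_lambda(
                rng.standard_normal((3, 2)), np.zeros((3, 1)), np.array([1.0]), k=5
            )


class TestScoreEncoders:
    def test_perfect_and_anti_correlated_predictions(self, rng):
        obs = rng.standard_normal((10, 2))
        r = score_encoders(obs, obs)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        r_neg = score_encoders(-obs, obs)
        np.testing.assert_allclose(r_neg, -1.0, atol=1e-12)
        np.testing.assert_allclose(score_encoders(-obs, obs, clamp_negative=True), 0.0)

    def test_hand_computed_pearson(self):
        r = score_encoders(
            np.array([[1.0], [2.0], [3.0]]), np.array([[2.0], [4.0], [7.0]])
        )
        assert r[0] == pytest.approx(0.99340, abs=1e-5)

    def test_zero_variance_column_reported_missing(self):
        pred = np.column_stack([np.ones(5), np.arange(5.0)])
        obs = np.column_stack([np.arange(5.0), np.arange(5.0)])
        r = score_encoders(pred, obs)
        assert np.isnan(r[0]) and r[1] == pytest.approx(1.0)


class TestCriticalCorrelation:
    @pytest.mark.parametrize(
        "df,expected", [(100, 0.3895), (200, 0.2807)]
    )
    def test_bonferroni_corrected_values(self, df, expected):
        assert critical_correlation(0.05 / 960, df) == pytest.approx(
            expected, abs=5e-5
        )

    def test_textbook_value_df2(self):
        assert critical_correlation(0.05, 2) == pytest.approx(0.950, abs=5e-4)

    def test_agrees_with_monte_carlo_null_quantile(self, rng):
        """r_crit matches the empirical 1-alpha quantile of |r| between
        independent Gaussian pairs of length df + 2."""
        alpha, df, n_sim = 0.05, 20, 40000
        x = rng.standard_normal((n_sim, df + 2))
        y = rng.standard_normal((n_sim, df + 2))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = np.sum(xc * yc, 1) / (
            np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
        )
        mc = np.quantile(np.abs(r), 1 - alpha)
        assert critical_correlation(alpha, df) == pytest.approx(mc, abs=0.02)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            critical_correlation(0.0, 10)
        with pytest.raises(ValueError):
            critical_correlation(0.05, 0)


class TestCompareEncoders:
    def test_df_convention_for_two_full_banks(self, rng):
        t, p, df = compare_encoders(
            rng.standard_normal(960), rng.standard_normal(960)
        )
        assert df == 1918

    def test_identical_groups_give_zero_t(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        t, p, _ = compare_encoders(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_match_closed_form_pooled_t(self):
        a = np.array([0.0, 0.001, -0.001, 0.0])
        b = np.array([1.0, 1.001, 0.999, 1.0])
        t, p, df = compare_encoders(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 4))
        assert t == pytest.approx(expected)
        assert p < 1e-6 and df == 6

    def test_insufficient_units(self):
        with pytest.raises(ValueError):
            compare_encoders(np.array([0.1]), np.array([0.2, 0.3]))


class TestAssignComplexity:
    def test_argmax_per_unit(self):
        scores = np.array([[0.1, 0.5], [0.9, 0.5], [0.3, 0.2]])
        result = assign_complexity(scores)
        assert result.labels.tolist() == [1, 0]
        assert result.tie_mask.tolist() == [False, True]  # 0.5 tie -> lowest index

    def test_histogram_by_region(self):
        scores = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        result = assign_complexity(scores, region_labels=["V1", "V1", "IT"])
        assert result.histogram.loc["V1", 0] == 1
        assert result.histogram.loc["V1", 1] == 1

    def test_all_missing_unit_raises(self):
        scores = np.array([[np.nan, 0.1], [np.nan, 0.2]])
        with pytest.raises(ValueError):
            assign_complexity(scores)
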