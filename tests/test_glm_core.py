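"""Model fitting, metrics and nested-model tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from predsel import (
    RankDeficiencyError,
    SeparationError,
    adjusted_r2,
    c_statistic,
    f_change_test,
    fit_linear,
    fit_logistic,
    likelihood_ratio_test,
    standardized_estimates,
)


def make_xy(rng, n, p, beta=None, noise=1.0):
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    y = pd.Series(X.to_numpy() @ beta + noise * rng.standard_normal(n), name="y")
    return y, X


class TestFitLinear:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(10, dtype=float)
        y = pd.Series(2 * x, name="y")
        fit = fit_linear(y, pd.DataFrame({"x": x}))
        assert fit.estimates["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_outcome_gives_zero_slopes(self, rng):
        y, X = make_xy(rng, 30, 3)
        fit = fit_linear(pd.Series(np.full(30, 5.0), name="y"), X)
        assert all(abs(v) < 1e-12 for v in fit.estimates.values())

    def test_matches_normal_equations_oracle(self, rng):
        y, X = make_xy(rng, 20, 3, beta=[1.0, -0.5, 0.2])
        fit = fit_linear(y, X)
        design = np.column_stack([np.ones(20), X])
        oracle = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
        assert fit.intercept == pytest.approx(oracle[0], abs=1e-8)
        for i, name in enumerate(X.columns):
            assert fit.estimates[name] == pytest.approx(oracle[i + 1], abs=1e-8)

    def test_rank_deficient_design_names_dependent_column(self, rng):
        y, X = make_xy(rng, 25, 2)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(RankDeficiencyError) as err:
            fit_linear(y, X)
        assert set(err.value.columns) & {"x0", "dup"}

    def test_residuals_orthogonal_to_design(self, rng):
        y, X = make_xy(rng, 80, 4, beta=[1, 0, -1, 0.5])
        fit = fit_linear(y, X)
        resid = y.to_numpy() - fit.predict(X)
        design = np.column_stack([np.ones(80), X])
        assert np.abs(design.T @ resid).max() < 1e-6


class TestFitLogistic:
    def test_null_covariate_coefficient_near_zero(self, rng):
        n = 2000
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = pd.Series(rng.binomial(1, 0.5, n).astype(float), name="y")
        fit = fit_logistic(y, X)
        assert abs(fit.estimates["x"]) < 0.15
        assert fit.pvalues["x"] > 0.01

    def test_intercept_only_equals_logit_of_prevalence(self):
        y = pd.Series([1.0] * 30 + [0.0] * 70, name="y")
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.intercept == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = pd.Series((x > 0).astype(float), name="y")
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_one_class_outcome_rejected(self, rng):
        X = pd.DataFrame({"x": rng.standard_normal(20)})
        with pytest.raises(ValueError):
            fit_logistic(pd.Series(np.ones(20), name="y"), X)


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 50, 3) == pytest.approx(1.0)

    def test_zero_r2_zero_covariates_stays_zero(self):
        assert adjusted_r2(0.0, 100, 0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # 1 - 0.5 * 10 / 9
        assert adjusted_r2(0.5, 11, 1) == pytest.approx(0.444444444, abs=1e-9)

    def test_never_exceeds_r2(self, rng):
        for _ in range(50):
            r2 = rng.uniform(0, 1)
            n = int(rng.integers(10, 200))
            p = int(rng.integers(1, 8))
            assert adjusted_r2(r2, n, p) <= r2 + 1e-12

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 4, 3)


class TestCStatistic:
    def test_constant_scores_are_uninformative(self):
        assert c_statistic([1, 1, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_ordering_is_one(self):
        assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_tied_scores_count_half(self):
        assert c_statistic([0.9, 0.3, 0.6, 0.6], [1, 0, 1, 0]) == pytest.approx(0.875)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([0.5, 0.6], [1, 1])

    def test_equals_mann_whitney_u_oracle(self, rng):
        for _ in range(200):
            n1, n0 = rng.integers(2, 15, size=2)
            scores = np.round(rng.standard_normal(n1 + n0), 1)  # rounding forces ties
            labels = np.array([1] * n1 + [0] * n0)
            u = stats.mannwhitneyu(scores[:n1], scores[n1:], alternative="two-sided").statistic
            assert c_statistic(scores, labels) == pytest.approx(u / (n1 * n0), abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False).map(lambda v: round(v, 3)),
            min_size=4,
            max_size=30,
        ),
        st.data(),
    )
    def test_invariant_under_monotone_transform(self, scores, data):
        labels = data.draw(
            st.lists(st.sampled_from([0, 1]), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        raw = c_statistic(scores, labels)
        warped = c_statistic(np.exp(0.5 * np.asarray(scores)), labels)
        assert warped == pytest.approx(raw, abs=1e-12)


class TestNestedTests:
    def test_identical_linear_models_give_p_one(self, rng):
        y, X = make_xy(rng, 40, 2, beta=[1, 1])
        fit = fit_linear(y, X)
        assert f_change_test(fit, fit) == pytest.approx(1.0)

    def test_strong_predictor_improves_fit(self, rng):
        y, X = make_xy(rng, 200, 2, beta=[1.0, 0.0])
        reduced = fit_linear(y, X[["x1"]])
        full = fit_linear(y, X)
        assert f_change_test(reduced, full) < 1e-3

    def test_f_change_null_p_is_uniform(self, rng):
        pvals = []
        for _ in range(500):
            y, X = make_xy(rng, 50, 2, beta=[0.8, 0.0])
            reduced = fit_linear(y, X[["x0"]])
            full = fit_linear(y, X)
            pvals.append(f_change_test(reduced, full))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_mismatched_rows_rejected(self, rng):
        y, X = make_xy(rng, 40, 2)
        y2, X2 = make_xy(rng, 30, 2)
        with pytest.raises(ValueError):
            f_change_test(fit_linear(y2, X2[["x0"]]), fit_linear(y, X))

    def test_chi_square_tail_arithmetic(self):
        # a likelihood-ratio statistic of 3.84 on 1 df sits at p ~ 0.05
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_lrt_strong_predictor_significant(self, rng):
        n = 500
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-1.5 * x))
        y = pd.Series(rng.binomial(1, p).astype(float), name="y")
        X = pd.DataFrame({"x": x, "noise": rng.standard_normal(n)})
        reduced = fit_logistic(y, X[["noise"]])
        full = fit_logistic(y, X)
        assert likelihood_ratio_test(reduced, full) < 1e-3
        assert likelihood_ratio_test(full, full) == pytest.approx(1.0)


class TestStandardizedEstimates:
    def test_prestandardized_data_returns_raw_estimates(self, rng):
        n = 200
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.5 * x + 0.1 * rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=1)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_linear(df["y"], df[["x"]])
        std = standardized_estimates(fit, df)
        assert std["x"] == pytest.approx(fit.estimates["x"], abs=1e-10)

    def test_invariant_to_covariate_rescaling(self, rng):
        n = 100
        x = rng.standard_normal(n)
        y = pd.Series(2 * x + rng.standard_normal(n), name="y")
        df1 = pd.DataFrame({"y": y, "x": x})
        df2 = pd.DataFrame({"y": y, "x": 10 * x})
        s1 = standardized_estimates(fit_linear(df1["y"], df1[["x"]]), df1)
        s2 = standardized_estimates(fit_linear(df2["y"], df2[["x"]]), df2)
        assert s1["x"] == pytest.approx(s2["x"], abs=1e-10)

    def test_hand_computed_sd_ratio(self):
        df = pd.DataFrame({"y": [1.0, 3.0, 2.0, 5.0, 4.0], "x": [0.0, 2.0, 1.0, 4.0, 3.0]})
        fit = fit_linear(df["y"], df[["x"]])
        expected = fit.estimates["x"] * df["x"].std(ddof=1) / df["y"].std(ddof=1)
        assert standardized_estimates(fit, df)["x"] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_covariate_rejected(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(20), "x": rng.standard_normal(20)})
        fit = fit_linear(df["y"], df[["x"]])
        df["x"] = 1.0
        with pytest.raises(ValueError, match="x"):
            standardized_estimates(fit, df)
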