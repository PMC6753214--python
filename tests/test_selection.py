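"""Forward/backward/Lasso selection and the consensus rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from predsel import (
    SelectionOutcome,
    UnsupportedFamilyError,
    backward_select,
    consensus_select,
    forward_select,
    lasso_select,
)
from predsel.glm_core import fit_linear

from conftest import build_cohort


def orthogonal_cohort(rng, n, p, beta, noise=1.0, outcome="y"):
    """Cohort whose centered candidate columns are exactly orthogonal."""
    raw = rng.standard_normal((n, p))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    X = q * np.sqrt(n)  # unit-ish variance columns, exactly orthogonal, zero mean
    y = X @ np.asarray(beta, float) + noise * rng.standard_normal(n)
    cols = {outcome: y}
    cols.update({f"x{i}": X[:, i] for i in range(p)})
    return build_cohort(cols, outcome=outcome)


class TestForwardBackward:
    def test_single_strong_predictor_selected_first(self, rng):
        cohort = orthogonal_cohort(rng, 120, 5, [1.5, 0, 0, 0, 0])
        out = forward_select(cohort, "y", [], [f"x{i}" for i in range(5)])
        assert out.selected[0] == "x0"

    def test_forced_baseline_survives_any_p(self, rng):
        n = 100
        pre = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = 1.0 * x + rng.standard_normal(n)  # baseline truly irrelevant
        cohort = build_cohort({"y": y, "y_pre": pre, "x": x}, outcome="y", forced={"y_pre"})
        out = backward_select(cohort, "y", ["y_pre"], ["x"])
        assert "y_pre" in out.final_fit.names
        assert "y_pre" not in out.selected

    def test_forward_matches_stepwise_oracle(self, rng):
        # one forward step re-derived independently: pick the candidate whose
        # addition minimizes the residual sum of squares
        cohort = orthogonal_cohort(rng, 80, 4, [0.8, 0.4, 0.0, 0.0])
        cands = [f"x{i}" for i in range(4)]
        out = forward_select(cohort, "y", [], cands)
        rss = {}
        for c in cands:
            rss[c] = fit_linear(cohort.data["y"], cohort.data[[c]]).rss
        assert out.selected[0] == min(rss, key=rss.get)

    def test_forward_equals_best_subset_on_orthogonal_designs(self, rng):
        # exhaustive enumeration oracle, <= 4 candidates
        for seed in range(5):
            r = np.random.default_rng(900 + seed)
            cohort = orthogonal_cohort(r, 60, 4, r.normal(0, 0.5, 4))
            cands = [f"x{i}" for i in range(4)]
            out = forward_select(cohort, "y", [], cands)
            k = len(out.selected)
            best, best_rss = None, np.inf
            for subset in itertools.combinations(cands, k):
                fit = fit_linear(cohort.data["y"], cohort.data[list(subset)])
                if fit.rss < best_rss:
                    best, best_rss = set(subset), fit.rss
            assert set(out.selected) == best

    def test_forward_and_backward_agree_on_orthogonal_designs(self, rng):
        for seed in range(5):
            r = np.random.default_rng(700 + seed)
            cohort = orthogonal_cohort(r, 100, 4, [0.7, 0.0, 0.35, 0.0])
            cands = [f"x{i}" for i in range(4)]
            fwd = forward_select(cohort, "y", [], cands)
            bwd = backward_select(cohort, "y", [], cands)
            assert set(fwd.selected) == set(bwd.selected)

    def test_backward_mostly_empties_under_null(self):
        empties = 0
        for seed in range(20):
            r = np.random.default_rng(1100 + seed)
            cohort = orthogonal_cohort(r, 200, 4, [0, 0, 0, 0])
            out = backward_select(cohort, "y", [], [f"x{i}" for i in range(4)])
            empties += not out.selected
        # family-wise null: P(all four p >= 0.05) ~ 0.81
        assert empties >= 12


class TestLasso:
    def test_binary_outcome_rejected(self, rng):
        y = (rng.standard_normal(40) > 0).astype(float)
        cohort = build_cohort(
            {"y": y, "x": rng.standard_normal(40)}, outcome="y", binary={"y"}
        )
        with pytest.raises(UnsupportedFamilyError):
            lasso_select(cohort, "y", [], ["x"])

    def test_huge_penalty_selects_nothing(self, rng):
        cohort = orthogonal_cohort(rng, 80, 3, [1.0, 0.5, 0.0])
        out = lasso_select(cohort, "y", [], ["x0", "x1", "x2"], alpha_override=1e6)
        assert out.selected == []

    def test_zero_penalty_recovers_ols_support_and_estimates(self, rng):
        cohort = orthogonal_cohort(rng, 80, 3, [1.0, -0.8, 0.6], noise=0.3)
        cands = ["x0", "x1", "x2"]
        out = lasso_select(cohort, "y", [], cands, alpha_override=1e-12)
        assert out.selected == cands
        ols = fit_linear(cohort.data["y"], cohort.data[cands])
        for c in cands:
            assert out.estimates[c] == pytest.approx(ols.estimates[c], abs=1e-6)

    def test_support_matches_soft_threshold_oracle(self, rng):
        # on an orthogonal standardized design the Lasso coefficient is
        # sign(b)*max(|b| - lam, 0) with b = X'y/n, so the selected support
        # is exactly {j : |X_j'y|/n > lam}
        cohort = orthogonal_cohort(rng, 100, 4, [0.9, 0.5, 0.25, 0.0], noise=0.5)
        cands = [f"x{i}" for i in range(4)]
        data = cohort.data
        y = data["y"].to_numpy()
        yc = y - y.mean()
        for lam in (0.02, 0.1, 0.3, 0.6, 1.0):
            expected = []
            for c in cands:
                x = data[c].to_numpy()
                xc = (x - x.mean())
                xs = xc / xc.std(ddof=1)
                if abs(xs @ yc) / len(y) > lam:
                    expected.append(c)
            out = lasso_select(cohort, "y", [], cands, alpha_override=lam)
            assert out.selected == expected, f"lam={lam}"

    def test_cv_lasso_finds_true_support_with_refit_pvalues(self, rng):
        cohort = orthogonal_cohort(rng, 200, 5, [0.8, 0.8, 0, 0, 0], noise=0.7)
        out = lasso_select(cohort, "y", [], [f"x{i}" for i in range(5)], seed=1)
        assert {"x0", "x1"} <= set(out.selected)
        assert out.pvalues["x0"] < 1e-6


def _outcome(method, pvals):
    return SelectionOutcome(
        method=method,
        candidates=["A", "B"],
        selected=list(pvals),
        pvalues=dict(pvals),
        estimates={k: 1.0 for k in pvals},
    )


class TestConsensus:
    def test_two_weak_one_strong_retained(self):
        outs = [
            _outcome("forward", {"A": 0.01}),
            _outcome("backward", {"A": 0.0005}),
            _outcome("lasso", {}),
        ]
        assert consensus_select(outs).retained == ["A"]

    def test_single_method_selection_rejected(self):
        outs = [
            _outcome("forward", {"A": 0.01}),
            _outcome("backward", {}),
            _outcome("lasso", {}),
        ]
        assert consensus_select(outs).retained == []

    def test_two_weak_without_strong_rejected(self):
        outs = [
            _outcome("forward", {"A": 0.01}),
            _outcome("backward", {"A": 0.02}),
            _outcome("lasso", {}),
        ]
        assert consensus_select(outs).retained == []

    def test_unanimous_strong_retained(self):
        outs = [_outcome(m, {"A": 0.0005}) for m in ("forward", "backward", "lasso")]
        result = consensus_select(outs)
        assert result.retained == ["A"]
        assert result.strong_count["A"] == 3

    def test_two_method_rule_requires_both_weak(self):
        outs = [_outcome("forward", {"A": 0.0005}), _outcome("backward", {})]
        assert consensus_select(outs).retained == []
        outs = [_outcome("forward", {"A": 0.0005}), _outcome("backward", {"A": 0.04})]
        assert consensus_select(outs).retained == ["A"]

    def test_mismatched_universes_rejected(self):
        a = _outcome("forward", {"A": 0.01})
        b = SelectionOutcome("backward", ["A", "C"], [], {}, {})
        with pytest.raises(ValueError):
            consensus_select([a, b, _outcome("lasso", {})])

    def test_retained_subset_of_union_of_selected(self):
        outs = [
            _outcome("forward", {"A": 0.0005, "B": 0.2}),
            _outcome("backward", {"B": 0.01}),
            _outcome("lasso", {"A": 0.02}),
        ]
        result = consensus_select(outs)
        union = set().union(*(o.selected for o in outs))
        assert set(result.retained) <= union

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(1e-6, 0.999, allow_nan=False), min_size=3, max_size=3
        ),
        st.integers(0, 2),
    )
    def test_monotone_in_pvalues(self, pvals, which):
        def make(ps):
            return [
                _outcome(m, {"A": p})
                for m, p in zip(("forward", "backward", "lasso"), ps)
            ]

        before = "A" in consensus_select(make(pvals)).retained
        lowered = list(pvals)
        lowered[which] = lowered[which] / 10
        after = "A" in consensus_select(make(lowered)).retained
        assert after >= before  # lowering a p-value never drops a candidate
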