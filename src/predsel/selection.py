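"""Stage 3 — forward, backward and Lasso selection plus the consensus rule.

A predictor survives only if it is at least weakly significant
(p < 0.05) in two of the three selection processes and at least highly
significant (p < 0.001) in one of them.  For binary outcomes the Lasso
process does not apply (it is run for linear regression only), and the
rule tightens to 2-of-2 weak plus one strong.

All three processes keep the forced covariates (the baseline value of the
outcome) in every model; forced covariates are never counted as
"selected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .glm_core import FitResult, UnsupportedFamilyError, fit_family, fit_linear, nested_test
from .tabular_io import Cohort


@dataclass
class SelectionOutcome:
    method: str                    # "forward" | "backward" | "lasso"
    candidates: list[str]          # the universe the method searched
    selected: list[str]
    pvalues: dict[str, float]      # per selected name, from the final/refit model
    estimates: dict[str, float]
    final_fit: FitResult | None = None


@dataclass
class ConsensusResult:
    weak_count: dict[str, int]
    strong_count: dict[str, int]
    retained: list[str]
    n_methods: int


def _model_frame(cohort: Cohort, outcome: str, forced: list[str], candidates: list[str]):
    cols = [outcome] + list(forced) + list(candidates)
    data = cohort.complete_cases(cols)
    return data


def forward_select(
    cohort: Cohort,
    outcome: str,
    forced: list[str],
    candidates: list[str],
    entry_alpha: float = 0.05,
) -> SelectionOutcome:
    """Greedy forward inclusion by nested-model tests.

    Starting from the forced-only model, repeatedly adds the candidate
    with the smallest F-change (linear) or likelihood-ratio (logistic)
    p-value while that p-value is below `entry_alpha`.
    """
    family = cohort.family_of(outcome)
    data = _model_frame(cohort, outcome, forced, candidates)
    y = data[outcome]
    current: list[str] = []
    remaining = list(candidates)
    base = fit_family(y, data[list(forced)], family)
    while remaining:
        best_name, best_p, best_fit = None, np.inf, None
        for cand in remaining:
            fit = fit_family(y, data[list(forced) + current + [cand]], family)
            p = nested_test(base, fit)
            if p < best_p:
                best_name, best_p, best_fit = cand, p, fit
        if best_p >= entry_alpha:
            break
        current.append(best_name)
        remaining.remove(best_name)
        base = best_fit
    final = base
    return SelectionOutcome(
        method="forward",
        candidates=list(candidates),
        selected=list(current),
        pvalues={nm: final.pvalues[nm] for nm in current},
        estimates={nm: final.estimates[nm] for nm in current},
        final_fit=final,
    )


def backward_select(
    cohort: Cohort,
    outcome: str,
    forced: list[str],
    candidates: list[str],
    stay_alpha: float = 0.05,
) -> SelectionOutcome:
    """Backward elimination by Wald p-values.

    Starts from the full model and repeatedly drops the non-forced
    covariate with the largest p >= `stay_alpha`.  Forced covariates stay
    regardless of significance.
    """
    family = cohort.family_of(outcome)
    data = _model_frame(cohort, outcome, forced, candidates)
    y = data[outcome]
    current = list(candidates)
    fit = fit_family(y, data[list(forced) + current], family)
    while current:
        worst = max(current, key=lambda nm: fit.pvalues[nm])
        if fit.pvalues[worst] < stay_alpha:
            break
        current.remove(worst)
        fit = fit_family(y, data[list(forced) + current], family)
    return SelectionOutcome(
        method="backward",
        candidates=list(candidates),
        selected=list(current),
        pvalues={nm: fit.pvalues[nm] for nm in current},
        estimates={nm: fit.estimates[nm] for nm in current},
        final_fit=fit,
    )


def lasso_select(
    cohort: Cohort,
    outcome: str,
    forced: list[str],
    candidates: list[str],
    seed: int = 0,
    cv_folds: int = 10,
    alpha_override: float | None = None,
) -> SelectionOutcome:
    """L1-penalized selection for continuous outcomes.

    Forced covariates are left unpenalized by partialling them (and the
    intercept) out of the outcome and of every candidate first; the Lasso
    then runs on the standardized candidate residuals with its penalty
    chosen by 10-fold cross-validation (or fixed via `alpha_override`).
    Because the Lasso itself yields no p-values, significance for the
    consensus rule comes from an unpenalized refit on the selected set.
    """
    family = cohort.family_of(outcome)
    if family != "linear":
        raise UnsupportedFamilyError("Lasso selection applies to linear regression only")
    data = _model_frame(cohort, outcome, forced, candidates)
    y = data[outcome].to_numpy(dtype=float)

    # Frisch–Waugh: residualize on [1, forced]
    Z = np.column_stack([np.ones(len(data))] + [data[f].to_numpy(float) for f in forced])
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    ry = y - Z @ beta_y
    R = np.empty((len(data), len(candidates)))
    for j, cand in enumerate(candidates):
        x = data[cand].to_numpy(dtype=float)
        bx, *_ = np.linalg.lstsq(Z, x, rcond=None)
        R[:, j] = x - Z @ bx
    sds = R.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    Rs = R / sds

    if alpha_override is not None:
        model = Lasso(alpha=alpha_override, fit_intercept=False, max_iter=100000)
    else:
        cv = KFold(n_splits=min(cv_folds, len(data)), shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, fit_intercept=False, max_iter=100000)
    model.fit(Rs, ry)
    selected = [candidates[j] for j in range(len(candidates)) if abs(model.coef_[j]) > 1e-10]

    if selected:
        refit = fit_linear(data[outcome], data[list(forced) + selected])
        pvals = {nm: refit.pvalues[nm] for nm in selected}
        ests = {nm: refit.estimates[nm] for nm in selected}
    else:
        refit = fit_linear(data[outcome], data[list(forced)])
        pvals, ests = {}, {}
    return SelectionOutcome(
        method="lasso",
        candidates=list(candidates),
        selected=selected,
        pvalues=pvals,
        estimates=ests,
        final_fit=refit,
    )


def consensus_select(
    outcomes: list[SelectionOutcome],
    weak_alpha: float = 0.05,
    strong_alpha: float = 0.001,
) -> ConsensusResult:
    """Retain predictors selected consistently across the processes.

    With three processes: weakly significant (p < weak_alpha) in at least
    two and highly significant (p < strong_alpha) in at least one.  With
    two processes (logistic pipelines, where Lasso does not apply): weakly
    significant in both and highly significant in one.
    """
    if len(outcomes) not in (2, 3):
        raise ValueError("consensus needs the outcomes of 2 or 3 selection processes")
    universe = outcomes[0].candidates
    for oc in outcomes[1:]:
        if set(oc.candidates) != set(universe):
            raise ValueError("selection processes searched different candidate universes")
    weak, strong = {}, {}
    for cand in universe:
        weak[cand] = sum(
            1 for oc in outcomes if cand in oc.selected and oc.pvalues[cand] < weak_alpha
        )
        strong[cand] = sum(
            1 for oc in outcomes if cand in oc.selected and oc.pvalues[cand] < strong_alpha
        )
    need_weak = 2 if len(outcomes) == 3 else len(outcomes)
    retained = [c for c in universe if weak[c] >= need_weak and strong[c] >= 1]
    return ConsensusResult(
        weak_count=weak, strong_count=strong, retained=retained, n_methods=len(outcomes)
    )


def consensus_to_frame(result: ConsensusResult) -> pd.DataFrame:
    """Per-candidate weak/strong counts and decisions as a table."""
    return pd.DataFrame(
        {
            "candidate": list(result.weak_count),
            "weak_count": list(result.weak_count.values()),
            "strong_count": list(result.strong_count.values()),
            "retained": [c in result.retained for c in result.weak_count],
        }
    )
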