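"""Stage 4 — model characterization, robustness, and bootstrap optimism.

Characterization marks models as irrelevant when their explanatory power
is too low (R²adj < 0.3 for linear outcomes, c-statistic < 0.6 for binary
ones).  Robustness re-checks the metric after removing rows in aberrant
ranges of the model function.  Optimism is estimated by re-running the
*entire* selection pipeline on bootstrap resamples and scoring each
resample-built model back on the original cohort: selection on the same
data it is judged by inflates apparent performance, and the mean
(apparent - test) gap across replicates estimates that inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm_core import FitResult, adjusted_r2, c_statistic, fit_family, nested_test, r_squared, standardized_estimates
from .tabular_io import Cohort, RunConfig


@dataclass
class PerformanceMetrics:
    family: str
    r2: float | None = None
    r2_adj: float | None = None
    c_statistic: float | None = None

    @property
    def headline(self) -> float:
        return self.r2_adj if self.family == "linear" else self.c_statistic


@dataclass
class RelevanceVerdict:
    metrics: PerformanceMetrics
    relevant: bool
    threshold: float


@dataclass
class RobustnessResult:
    robust: bool
    before: float
    after: float
    n_excluded: int
    n_after: int


@dataclass
class OptimismReport:
    family: str
    apparent: float
    optimism: float
    corrected: float
    apparent_b: list[float]
    test_b: list[float]
    B: int
    seed: int
    n_skipped: int = 0


def model_metric(fit: FitResult, cohort: Cohort, outcome: str | None = None) -> float:
    """Headline metric of `fit` evaluated on `cohort` (R²adj or c-statistic).

    On data other than the training rows the linear R² may be negative;
    it is still adjusted with the model's own covariate count.
    """
    outcome = outcome or fit.outcome
    data = cohort.complete_cases([outcome] + fit.names)
    if fit.family == "linear":
        r2 = r_squared(fit, data, outcome)
        return float(adjusted_r2(r2, len(data), fit.k))
    return c_statistic(fit.predict(data), data[outcome])


def characterize_model(fit: FitResult, cohort: Cohort, config: RunConfig) -> RelevanceVerdict:
    """Compute the family-appropriate metric and the relevance verdict."""
    outcome = fit.outcome or config.outcome
    data = cohort.complete_cases([outcome] + fit.names)
    if fit.family == "linear":
        r2 = float(r_squared(fit, data, outcome))
        r2a = float(adjusted_r2(r2, len(data), fit.k))
        metrics = PerformanceMetrics(family="linear", r2=r2, r2_adj=r2a)
        threshold = config.r2_relevance
        relevant = bool(r2a >= threshold)
    else:
        c = c_statistic(fit.predict(data), data[outcome])
        metrics = PerformanceMetrics(family="logistic", c_statistic=c)
        threshold = config.c_relevance
        relevant = bool(c >= threshold)
    return RelevanceVerdict(metrics=metrics, relevant=relevant, threshold=threshold)


def incremental_inclusion(
    cohort: Cohort,
    outcome: str,
    forced: list[str],
    retained: list[str],
    order: list[str] | None = None,
) -> list[dict]:
    """Re-enter retained covariates one at a time, most influential first.

    Influence order defaults to descending |standardized estimate| from
    the full model.  Each step reports the nested-test p-value (F-change
    for linear, likelihood ratio for logistic) of adding that covariate
    to the model built so far.
    """
    if not retained:
        raise ValueError("retained set is empty")
    family = cohort.family_of(outcome)
    cols = [outcome] + list(forced) + list(retained)
    data = cohort.complete_cases(cols)
    y = data[outcome]
    if order is None:
        full = fit_family(y, data[list(forced) + list(retained)], family)
        std = standardized_estimates(full, data)
        order = sorted(retained, key=lambda nm: -abs(std[nm]))
    current: list[str] = []
    base = fit_family(y, data[list(forced)], family)
    steps = []
    for name in order:
        fit = fit_family(y, data[list(forced) + current + [name]], family)
        p = nested_test(base, fit)
        steps.append(
            {
                "covariate": name,
                "p": p,
                "estimate": fit.estimates[name],
                "k": fit.k,
            }
        )
        current.append(name)
        base = fit
    return steps


def robustness_check(
    fit: FitResult,
    cohort: Cohort,
    rule: dict | None = None,
    retention_fraction: float = 0.5,
    relevance_threshold: float | None = None,
) -> RobustnessResult:
    """Refit after excluding aberrant ranges of the model function.

    The default rule drops rows whose prediction falls outside the
    [5th, 95th] percentile of predictions or whose standardized residual
    exceeds 2.5 in magnitude.  The model is robust when the refitted
    metric keeps at least `retention_fraction` of the original metric and
    stays above the relevance threshold; a metric that collapses (for
    example R²adj 0.57 -> 0.10) marks the model as not robust, while one
    that holds (0.34 -> 0.34) passes.
    """
    rule = rule or {}
    lo, hi = rule.get("prediction_percentiles", (5, 95))
    zmax = rule.get("residual_z", 2.5)
    outcome = fit.outcome
    data = cohort.complete_cases([outcome] + fit.names)
    pred = fit.predict(data)
    y = data[outcome].to_numpy(dtype=float)
    if fit.family == "linear":
        scale = np.sqrt(fit.residual_variance) if fit.residual_variance else 1.0
        resid_z = (y - pred) / (scale if scale > 0 else 1.0)
    else:
        p = np.clip(pred, 1e-10, 1 - 1e-10)
        resid_z = (y - p) / np.sqrt(p * (1 - p))
    plo, phi = np.percentile(pred, [lo, hi])
    aberrant = (pred < plo) | (pred > phi) | (np.abs(resid_z) > zmax)
    keep = data.index[~aberrant]
    min_rows = max(20, 5 * fit.k)
    if len(keep) < min_rows:
        raise ValueError(f"exclusion rule leaves {len(keep)} rows; need >= {min_rows}")
    before = model_metric(fit, cohort)
    sub = cohort.subset(keep)
    refit = fit_family(sub.data.loc[:, outcome], sub.data.loc[:, fit.names], fit.family)
    after = model_metric(refit, sub)
    if relevance_threshold is None:
        relevance_threshold = 0.3 if fit.family == "linear" else 0.6
    robust = bool(after >= retention_fraction * before and after >= relevance_threshold)
    return RobustnessResult(
        robust=robust,
        before=float(before),
        after=float(after),
        n_excluded=int(aberrant.sum()),
        n_after=len(keep),
    )


def _resample(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    idx = rng.integers(0, cohort.n, size=cohort.n)
    df = cohort.data.iloc[idx].reset_index(drop=True)
    df[cohort.id_var] = [f"bs{i}" for i in range(len(df))]  # resampling duplicates ids
    return Cohort(df, list(cohort.specs))


def bootstrap_optimism(
    cohort: Cohort,
    outcome: str,
    forced: list[str],
    candidates: list[str],
    pipeline,
    B: int,
    seed: int,
) -> OptimismReport:
    """Whole-pipeline bootstrap estimate of selection optimism.

    `pipeline` is any callable ``(cohort, seed) -> FitResult | None``
    running the complete stage 1-3 procedure (screen, factor-reduce,
    triple-select, consensus, fit); ``None`` or an empty consensus falls
    back to the forced-only model.  For each of B resamples the pipeline
    is re-run from scratch; ``apparent_b`` is the resample-built model's
    metric on its own resample and ``test_b`` the same model's metric on
    the original cohort.  optimism = mean(apparent_b - test_b);
    corrected = apparent - optimism.  Logistic resamples missing an
    outcome class are skipped and counted.
    """
    if B < 1:
        raise ValueError("bootstrap needs B >= 1")
    family = cohort.family_of(outcome)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(B + 1)]
    rng = np.random.default_rng(seed)

    def run(c: Cohort, s: int) -> FitResult:
        fit = pipeline(c, s)
        if fit is None:
            data = c.complete_cases([outcome] + list(forced))
            fit = fit_family(data[outcome], data[list(forced)], family)
        return fit

    apparent_fit = run(cohort, child_seeds[0])
    apparent = model_metric(apparent_fit, cohort, outcome)

    apparent_b, test_b, skipped = [], [], 0
    for b in range(B):
        sample = _resample(cohort, rng)
        if family == "logistic" and sample.data[outcome].nunique() < 2:
            skipped += 1
            continue
        try:
            fit_b = run(sample, child_seeds[b + 1])
            apparent_b.append(model_metric(fit_b, sample, outcome))
            test_b.append(model_metric(fit_b, cohort, outcome))
        except Exception:
            skipped += 1
    if not apparent_b:
        raise RuntimeError("all bootstrap replicates failed")
    optimism = float(np.mean(np.array(apparent_b) - np.array(test_b)))
    return OptimismReport(
        family=family,
        apparent=float(apparent),
        optimism=optimism,
        corrected=float(apparent - optimism),
        apparent_b=[float(v) for v in apparent_b],
        test_b=[float(v) for v in test_b],
        B=B,
        seed=seed,
        n_skipped=skipped,
    )
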