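"""Linear and logistic model fitting plus the shared metrics and tests.

Every later pipeline stage consumes :class:`FitResult`: screening fits
bivariable models, the selection processes compare nested fits by
F-change / likelihood-ratio tests, validation computes R²adj and the
c-statistic, and the nomogram evaluates the fitted equation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

LOGIT_TOL = 1e-8
LOGIT_MAXITER = 100
#: |standardized coefficient| beyond which a logistic fit is treated as
#: separated (estimates diverging).
SEPARATION_BOUND = 15.0


class RankDeficiencyError(ValueError):
    """Design matrix is not full rank; names the dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient in column(s): {', '.join(self.columns)}")


class SeparationError(ValueError):
    """Logistic outcome is (quasi-)perfectly separated by the covariates."""


class UnsupportedFamilyError(TypeError):
    """Operation called with a model family it does not apply to."""


@dataclass
class FitResult:
    """A fitted linear or logistic regression model."""

    family: str                      # "linear" | "logistic"
    outcome: str | None
    intercept: float
    names: list[str]                 # covariates in design order
    estimates: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]        # Wald p per covariate
    n: int
    k: int                           # number of fitted covariates
    log_likelihood: float
    rss: float | None = None         # linear only
    residual_variance: float | None = None
    standardized: dict[str, float] | None = None

    def coef_vector(self) -> np.ndarray:
        return np.array([self.estimates[n] for n in self.names])

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.names].to_numpy(dtype=float)
        return self.intercept + X @ self.coef_vector()

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predictions on the response scale (probabilities for logistic)."""
        lp = self.linear_predictor(data)
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-lp))
        return lp

    def to_json(self) -> str:
        d = {
            "family": self.family,
            "outcome": self.outcome,
            "intercept": self.intercept,
            "names": self.names,
            "estimates": self.estimates,
            "se": self.se,
            "pvalues": self.pvalues,
            "n": self.n,
            "k": self.k,
            "log_likelihood": self.log_likelihood,
            "rss": self.rss,
            "residual_variance": self.residual_variance,
            "standardized": self.standardized,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        return cls(**json.loads(text))


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return mat, names


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    # QR with pivoting: columns pivoted past the numerical rank are the
    # linearly dependent ones.
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        labels = ["intercept"] + names
        dep = [labels[j] for j in piv[rank:]]
        raise RankDeficiencyError(dep)


def fit_linear(y: pd.Series, X: pd.DataFrame) -> FitResult:
    """Ordinary least squares with t-based Wald p-values.

    Requires complete data and n > p + 1; a rank-deficient design raises
    :class:`RankDeficiencyError` naming the dependent columns.
    """
    design, names = _design(X)
    n, pcols = design.shape
    if n <= pcols:
        raise ValueError(f"need n > p + 1 (n={n}, covariates={pcols - 1})")
    if np.isnan(design).any() or np.asarray(y, float).ndim != 1 or pd.isna(y).any():
        raise ValueError("fit_linear requires complete data")
    _check_rank(design, names)
    res = sm.OLS(np.asarray(y, dtype=float), design).fit()
    params = res.params
    return FitResult(
        family="linear",
        outcome=getattr(y, "name", None),
        intercept=float(params[0]),
        names=names,
        estimates={nm: float(params[i + 1]) for i, nm in enumerate(names)},
        se={nm: float(res.bse[i + 1]) for i, nm in enumerate(names)},
        pvalues={nm: float(res.pvalues[i + 1]) for i, nm in enumerate(names)},
        n=n,
        k=len(names),
        log_likelihood=float(res.llf),
        rss=float(res.ssr),
        residual_variance=float(res.ssr / res.df_resid) if res.df_resid > 0 else 0.0,
    )


def fit_logistic(y: pd.Series, X: pd.DataFrame) -> FitResult:
    """Maximum-likelihood logistic regression (Newton iterations).

    Converges when the parameter update falls below 1e-8 (at most 100
    iterations); Wald p-values use the normal approximation.  Perfect or
    quasi-perfect separation raises :class:`SeparationError`.
    """
    design, names = _design(X)
    n = design.shape[0]
    yv = np.asarray(y, dtype=float)
    classes = np.unique(yv)
    if len(classes) != 2:
        raise ValueError("logistic outcome must have exactly two observed classes")
    if n <= design.shape[1]:
        raise ValueError(f"need n > p + 1 (n={n}, covariates={len(names)})")
    yb = (yv == classes.max()).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            res = sm.Logit(yb, design).fit(
                method="newton", tol=LOGIT_TOL, maxiter=LOGIT_MAXITER, disp=0
            )
    except (PerfectSeparationError, ConvergenceWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit did not converge: {exc}") from exc
    params = res.params
    sds = X.std(ddof=1).to_numpy(dtype=float) if len(names) else np.array([])
    if len(names) and np.any(np.abs(params[1:] * sds) > SEPARATION_BOUND):
        raise SeparationError("coefficient magnitude indicates (quasi-)separation")
    return FitResult(
        family="logistic",
        outcome=getattr(y, "name", None),
        intercept=float(params[0]),
        names=names,
        estimates={nm: float(params[i + 1]) for i, nm in enumerate(names)},
        se={nm: float(res.bse[i + 1]) for i, nm in enumerate(names)},
        pvalues={nm: float(res.pvalues[i + 1]) for i, nm in enumerate(names)},
        n=n,
        k=len(names),
        log_likelihood=float(res.llf),
    )


def fit_family(y: pd.Series, X: pd.DataFrame, family: str) -> FitResult:
    if family == "linear":
        return fit_linear(y, X)
    if family == "logistic":
        return fit_logistic(y, X)
    raise UnsupportedFamilyError(f"unknown family {family!r}")


def r_squared(fit: FitResult, data: pd.DataFrame, outcome: str) -> float:
    """Coefficient of determination of `fit`'s predictions on `data`.

    On the training data this is the usual R²; on external data it may be
    negative (predictions worse than the mean).
    """
    y = data[outcome].to_numpy(dtype=float)
    yhat = fit.predict(data)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return 1.0 - np.sum((y - yhat) ** 2) / ss_tot


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R² penalized for model size: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def c_statistic(scores, labels) -> float:
    """Concordance between scores and a binary outcome (area under ROC).

    Over all positive/negative pairs: concordant pairs count 1, ties 0.5.
    0.5 means no discrimination, 1 perfect discrimination.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) != 2:
        raise ValueError("c-statistic requires both outcome classes present")
    return float(roc_auc_score(labels, scores))


def f_change_test(reduced: FitResult, full: FitResult) -> float:
    """F test for the improvement of a nested linear model.

    Compares residual sums of squares of two linear fits on the same rows;
    returns the p-value of the F statistic with (Δp, n - p_full - 1) df.
    """
    for fit in (reduced, full):
        if fit.family != "linear":
            raise UnsupportedFamilyError("F-change test applies to linear models")
    if reduced.n != full.n:
        raise ValueError("nested models must be fitted on the same rows")
    if not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested")
    df_diff = full.k - reduced.k
    if df_diff == 0:
        return 1.0
    df_resid = full.n - full.k - 1
    num = max(reduced.rss - full.rss, 0.0) / df_diff
    if full.rss <= 0:
        return 0.0 if num > 0 else 1.0
    f_stat = num / (full.rss / df_resid)
    return float(stats.f.sf(f_stat, df_diff, df_resid))


def likelihood_ratio_test(reduced: FitResult, full: FitResult) -> float:
    """Likelihood-ratio chi-square test for nested logistic models."""
    for fit in (reduced, full):
        if fit.family != "logistic":
            raise UnsupportedFamilyError("likelihood-ratio test applies to logistic models")
    if reduced.n != full.n:
        raise ValueError("nested models must be fitted on the same rows")
    if not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested")
    df_diff = full.k - reduced.k
    if df_diff == 0:
        return 1.0
    stat = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    return float(stats.chi2.sf(stat, df_diff))


def nested_test(reduced: FitResult, full: FitResult) -> float:
    """Family-appropriate nested-model test (F-change or likelihood ratio)."""
    if full.family == "linear":
        return f_change_test(reduced, full)
    return likelihood_ratio_test(reduced, full)


def standardized_estimates(fit: FitResult, cohort) -> dict[str, float]:
    """Scale-free coefficients for comparing predictor influence.

    Linear models: estimate * sd(x) / sd(y); logistic: estimate * sd(x)
    (per-SD change in the log odds).  Sample SDs use the complete-case
    rows of the fitted variables.
    """
    cols = list(fit.names) + ([fit.outcome] if fit.outcome else [])
    data = cohort.complete_cases(cols) if hasattr(cohort, "complete_cases") else cohort.dropna(subset=cols)
    out = {}
    sd_y = float(data[fit.outcome].std(ddof=1)) if fit.family == "linear" else 1.0
    if fit.family == "linear" and sd_y == 0:
        raise ValueError("outcome has zero variance")
    for name in fit.names:
        sd_x = float(data[name].std(ddof=1))
        if sd_x == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        out[name] = fit.estimates[name] * sd_x / sd_y
    return out
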