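"""Stage 1 — bivariable screening and relationship mapping.

Each candidate covariate is tested in a bivariable model of the outcome
that always includes the baseline value of that outcome (so a candidate
must add information beyond where the subject started).  Alongside the
test, the candidate/outcome relationship is mapped (Pearson vs Spearman
correlation, a quadratic term) to flag departures from the linearity the
downstream models assume; flags are advisory and logged, never automatic
exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .glm_core import fit_family, fit_linear
from .tabular_io import Cohort


@dataclass
class BivariableRecord:
    name: str
    p: float
    sign: int
    estimate: float
    pearson_r: float
    spearman_rho: float
    quadratic_p: float
    monotone_nonlinear: bool
    non_monotone: bool
    n: int
    retained: bool = False


def relationship_map(x, y) -> dict:
    """Diagnostics of the x-y relationship for model-validity screening.

    Returns Pearson r, Spearman rho and the Wald p of a quadratic term in
    y ~ x + x².  Flags: ``monotone_nonlinear`` when the rank correlation
    clearly exceeds the linear one (|rho| - |r| > 0.1); ``non_monotone``
    when the quadratic term is significant while rank correlation is weak
    (quadratic p < 0.05 and |rho| < 0.3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("relationship mapping needs n >= 10")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to relationship_map")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    xc = x - x.mean()  # centering reduces x / x² collinearity
    X = pd.DataFrame({"x": xc, "x2": xc**2})
    quad_p = fit_linear(pd.Series(y, name="y"), X).pvalues["x2"]
    return {
        "pearson_r": r,
        "spearman_rho": rho,
        "quadratic_p": quad_p,
        "monotone_nonlinear": bool(abs(rho) - abs(r) > 0.1),
        "non_monotone": bool(quad_p < 0.05 and abs(rho) < 0.3),
    }


def bivariable_screen(
    cohort: Cohort,
    outcome: str,
    baseline_outcome: str,
    candidates: list[str],
    alpha: float = 0.05,
) -> tuple[list[BivariableRecord], list[str]]:
    """Screen candidates in bivariable models with the baseline forced in.

    For every candidate fits ``outcome ~ baseline_outcome + candidate``
    (family chosen by the outcome scale) and keeps candidates whose Wald
    p-value is below `alpha`.  The baseline outcome itself is never a
    candidate and never screened out.
    """
    family = cohort.family_of(outcome)
    records: list[BivariableRecord] = []
    retained: list[str] = []
    for cand in candidates:
        if cand == outcome:
            raise ValueError(f"candidate {cand!r} is the outcome column")
        if cand == baseline_outcome:
            raise ValueError(f"candidate {cand!r} is the forced baseline outcome")
        data = cohort.complete_cases([outcome, baseline_outcome, cand])
        y = data[outcome]
        X = data[[baseline_outcome, cand]]
        fit = fit_family(y, X, family)
        rel = relationship_map(data[cand], data[outcome])
        rec = BivariableRecord(
            name=cand,
            p=fit.pvalues[cand],
            sign=int(np.sign(fit.estimates[cand])),
            estimate=fit.estimates[cand],
            n=len(data),
            **rel,
        )
        rec.retained = rec.p < alpha
        if rec.retained:
            retained.append(cand)
        records.append(rec)
    return records, retained


def records_to_frame(records: list[BivariableRecord]) -> pd.DataFrame:
    """Screening table as a DataFrame (for the CSV report bundle)."""
    return pd.DataFrame([asdict(r) for r in records])
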