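"""Prediction equations and point-based nomograms.

A nomogram turns a fitted regression equation into a paper tool: each
predictor value maps to points on a shared 0-100 scale (the most
influential predictor — largest |coefficient| x observed range — spans
the full 0-100), the points are summed, and the total maps back to the
predicted response.  All maps are affine, so reading the nomogram is
algebraically identical to evaluating the equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm_core import FitResult


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def evaluate_equation(fit: FitResult, values: dict[str, float], scale: str = "linear") -> float:
    """Evaluate the prediction equation at the given covariate values.

    Returns ``intercept + sum(estimate * value)``; with
    ``scale="response"`` the inverse link is applied (identity for linear
    models, inverse-logit for logistic ones).
    """
    missing = [n for n in fit.names if n not in values]
    if missing:
        raise ValueError(f"missing value(s) for covariate(s): {', '.join(missing)}")
    lp = fit.intercept + sum(fit.estimates[n] * values[n] for n in fit.names)
    if scale == "response" and fit.family == "logistic":
        return float(_expit(lp))
    return float(lp)


@dataclass
class PredictorScale:
    name: str
    estimate: float
    vmin: float
    vmax: float
    zero_end: float        # covariate value contributing 0 points
    influence: float       # |estimate| * (vmax - vmin)
    max_points: float      # points at the other end of the range

    def points(self, value: float) -> float:
        return 100.0 * abs(self.estimate) * abs(value - self.zero_end) * self._scale

    _scale: float = 1.0    # 1 / max influence, filled by the builder


@dataclass
class NomogramTable:
    family: str
    predictors: list[PredictorScale]
    base_lp: float         # linear predictor when every predictor sits at its zero end
    lp_per_point: float    # slope of the total-points -> linear-predictor map

    @property
    def max_total(self) -> float:
        return sum(p.max_points for p in self.predictors)

    def points_for(self, values: dict[str, float]) -> dict[str, float]:
        return {p.name: p.points(values[p.name]) for p in self.predictors}

    def total_points(self, values: dict[str, float]) -> float:
        return sum(self.points_for(values).values())

    def to_frame(self) -> pd.DataFrame:
        """Per-predictor breakpoint table (for CSV export)."""
        rows = []
        for p in self.predictors:
            for frac in np.linspace(0, 1, 11):
                v = p.vmin + frac * (p.vmax - p.vmin)
                rows.append({"predictor": p.name, "value": v, "points": p.points(v)})
        return pd.DataFrame(rows)


def build_nomogram(fit: FitResult, ranges: dict[str, tuple[float, float]]) -> NomogramTable:
    """Construct the point maps for every covariate of `fit`.

    `ranges` gives each covariate's (min, max) — typically the cohort's
    observed range or the instrument-defined range.  The zero-point end of
    each axis is the value minimizing that predictor's contribution
    (depends on the coefficient sign), so all point values are
    non-negative.
    """
    missing = [n for n in fit.names if n not in ranges]
    if missing:
        raise ValueError(f"missing range(s) for covariate(s): {', '.join(missing)}")
    influences = {}
    for name in fit.names:
        lo, hi = ranges[name]
        if not hi > lo:
            raise ValueError(f"zero-width range for {name!r}")
        influences[name] = abs(fit.estimates[name]) * (hi - lo)
    max_inf = max(influences.values())
    if max_inf == 0:
        raise ValueError("all coefficients are zero; nomogram is degenerate")
    predictors = []
    base_lp = fit.intercept
    for name in fit.names:
        lo, hi = ranges[name]
        b = fit.estimates[name]
        zero_end = lo if b >= 0 else hi
        base_lp += b * zero_end
        predictors.append(
            PredictorScale(
                name=name,
                estimate=b,
                vmin=lo,
                vmax=hi,
                zero_end=zero_end,
                influence=influences[name],
                max_points=100.0 * influences[name] / max_inf,
                _scale=1.0 / max_inf,
            )
        )
    return NomogramTable(
        family=fit.family,
        predictors=predictors,
        base_lp=base_lp,
        lp_per_point=max_inf / 100.0,
    )


def total_points_to_response(table: NomogramTable, total: float) -> float:
    """Map summed points back to the predicted response.

    Inverts the affine point maps exactly, so the read-off round-trips
    with :func:`evaluate_equation`.
    """
    if not (-1e-9 <= total <= table.max_total + 1e-9):
        raise ValueError(f"total points {total} outside reachable range [0, {table.max_total:.2f}]")
    lp = table.base_lp + table.lp_per_point * total
    if table.family == "logistic":
        return float(_expit(lp))
    return float(lp)


def render_chart(table: NomogramTable, path) -> None:
    """Optional horizontal-lines chart of the nomogram (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(table.predictors)
    fig, ax = plt.subplots(figsize=(8, 1.2 * (k + 3)))
    ax.hlines(k + 1, 0, 100, color="k")
    ax.text(-2, k + 1, "Points", ha="right", va="center")
    for t in range(0, 101, 10):
        ax.plot([t, t], [k + 0.93, k + 1.07], color="k", lw=0.8)
        ax.text(t, k + 1.2, str(t), ha="center", fontsize=8)
    for i, p in enumerate(table.predictors):
        y = k - i
        ax.hlines(y, 0, p.max_points, color="C0")
        ax.text(-2, y, p.name, ha="right", va="center")
        for frac in np.linspace(0, 1, 6):
            v = p.zero_end + frac * ((p.vmax if p.zero_end == p.vmin else p.vmin) - p.zero_end)
            pts = p.points(v)
            ax.plot([pts, pts], [y - 0.07, y + 0.07], color="C0", lw=0.8)
            ax.text(pts, y - 0.25, f"{v:g}", ha="center", fontsize=7)
    y = -1
    ax.hlines(y, 0, 100, color="C3")
    ax.text(-2, y, "Total points", ha="right", va="center")
    for frac in np.linspace(0, 1, 6):
        tp = frac * table.max_total
        x = 100 * frac
        ax.plot([x, x], [y - 0.07, y + 0.07], color="C3", lw=0.8)
        ax.text(x, y - 0.3, f"{tp:.0f}\n{total_points_to_response(table, tp):.2f}",
                ha="center", fontsize=7)
    ax.set_ylim(-2.2, k + 2)
    ax.set_xlim(-25, 105)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
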