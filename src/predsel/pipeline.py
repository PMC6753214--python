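"""End-to-end orchestration: screen → factor-reduce → triple-select →
consensus → fit → characterize → incremental → robustness → optimism →
nomogram, with a machine-readable report.

A single run seed fans out into independent per-stage substreams
(SeedSequence spawning), so changing the bootstrap replicate count never
perturbs the selection stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .collinearity import factor_decompose, pick_representatives
from .glm_core import FitResult, fit_family, standardized_estimates
from .nomogram import NomogramTable, build_nomogram, evaluate_equation
from .screening import bivariable_screen, records_to_frame
from .selection import (
    SelectionOutcome,
    backward_select,
    consensus_select,
    forward_select,
    lasso_select,
)
from .tabular_io import Cohort, RunConfig, validate_cohort
from .validation import (
    bootstrap_optimism,
    characterize_model,
    incremental_inclusion,
    robustness_check,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {original}")


def _substreams(seed: int, count: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(count)]


def select_predictors(cohort: Cohort, config: RunConfig, seed: int | None = None):
    """Stages 1-3: returns (records, groups, outcomes, consensus)."""
    seed = config.seed if seed is None else seed
    baseline = config.forced[0]
    records, retained = bivariable_screen(
        cohort, config.outcome, baseline, config.candidates, alpha=config.screen_alpha
    )
    bivar_p = {r.name: r.p for r in records}
    if len(retained) >= 2:
        groups = factor_decompose(cohort, retained)
        reduced = sorted(pick_representatives(groups, bivar_p), key=retained.index)
    else:
        groups = []
        reduced = list(retained)
    if not reduced:
        return records, groups, [], None
    family = cohort.family_of(config.outcome)
    outcomes = [
        forward_select(cohort, config.outcome, config.forced, reduced, config.weak_alpha),
        backward_select(cohort, config.outcome, config.forced, reduced, config.weak_alpha),
    ]
    if family == "linear":
        outcomes.append(
            lasso_select(cohort, config.outcome, config.forced, reduced, seed=seed)
        )
    consensus = consensus_select(outcomes, config.weak_alpha, config.strong_alpha)
    return records, groups, outcomes, consensus


def make_selection_pipeline(config: RunConfig):
    """Stage 1-3 procedure as a ``(cohort, seed) -> FitResult | None``
    callable, as required by the whole-pipeline bootstrap."""

    def run(cohort: Cohort, seed: int) -> FitResult | None:
        _, _, _, consensus = select_predictors(cohort, config, seed=seed)
        if consensus is None or not consensus.retained:
            return None
        data = cohort.complete_cases([config.outcome] + config.forced + consensus.retained)
        return fit_family(
            data[config.outcome],
            data[config.forced + consensus.retained],
            cohort.family_of(config.outcome),
        )

    return run


def format_equation(fit: FitResult, outcome: str | None = None, ndigits: int = 3) -> str:
    """Equation text in the Results style, e.g. ``y = 44.6 - 0.65*x``."""
    terms = [f"{round(fit.intercept, ndigits):g}"]
    for nm in fit.names:
        b = round(fit.estimates[nm], ndigits)
        terms.append(f"{'-' if b < 0 else '+'} ({abs(b):g}*{nm})")
    return f"{outcome or fit.outcome} = " + " ".join(terms)


@dataclass
class RunReport:
    """Everything one pipeline run produced, JSON-serializable."""

    config: dict
    seed: int
    validation: dict
    screening: list[dict]
    factor_groups: list[dict]
    selections: list[dict]
    consensus: dict | None
    skip_reason: str | None
    final_model: dict | None
    standardized: dict | None
    equation: str | None
    relevance: dict | None
    incremental: list[dict] | None
    robustness: dict | None
    optimism: dict | None
    nomogram: dict | None
    version: str = __version__

    def to_json(self) -> str:
        def _default(obj):
            if isinstance(obj, np.bool_):
                return bool(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            raise TypeError(f"not JSON serializable: {type(obj)}")

        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1, default=_default)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _nomogram_dict(table: NomogramTable) -> dict:
    return {
        "family": table.family,
        "base_lp": table.base_lp,
        "lp_per_point": table.lp_per_point,
        "max_total": table.max_total,
        "predictors": [
            {
                "name": p.name,
                "estimate": p.estimate,
                "range": [p.vmin, p.vmax],
                "zero_end": p.zero_end,
                "max_points": p.max_points,
            }
            for p in table.predictors
        ],
    }


def run_pipeline(cohort: Cohort, config: RunConfig) -> RunReport:
    """Run every stage and assemble the report.

    Stages after consensus are skipped (with the reason recorded) when the
    consensus set is empty.
    """
    seeds = _substreams(config.seed, 4)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # attach the stage name for diagnosis
            raise PipelineError(name, exc) from exc

    validation = stage("validate", validate_cohort, cohort, config)
    records, groups, outcomes, consensus = stage(
        "selection", select_predictors, cohort, config, seeds[0]
    )

    report = RunReport(
        config=dataclasses.asdict(config),
        seed=config.seed,
        validation=validation,
        screening=[dataclasses.asdict(r) for r in records],
        factor_groups=[
            {"index": g.index, "members": g.members, "representative": g.representative}
            for g in groups
        ],
        selections=[
            {
                "method": oc.method,
                "candidates": oc.candidates,
                "selected": oc.selected,
                "pvalues": oc.pvalues,
                "estimates": oc.estimates,
            }
            for oc in outcomes
        ],
        consensus=None,
        skip_reason=None,
        final_model=None,
        standardized=None,
        equation=None,
        relevance=None,
        incremental=None,
        robustness=None,
        optimism=None,
        nomogram=None,
    )
    if consensus is not None:
        report.consensus = {
            "weak_count": consensus.weak_count,
            "strong_count": consensus.strong_count,
            "retained": consensus.retained,
            "n_methods": consensus.n_methods,
        }
    if consensus is None or not consensus.retained:
        report.skip_reason = (
            "screening retained no candidates"
            if consensus is None
            else "consensus retained no predictors"
        )
        return report

    family = cohort.family_of(config.outcome)
    cols = [config.outcome] + config.forced + consensus.retained
    data = cohort.complete_cases(cols)
    fit = stage(
        "fit", fit_family, data[config.outcome], data[config.forced + consensus.retained], family
    )
    fit.standardized = stage("standardize", standardized_estimates, fit, cohort)
    report.final_model = json.loads(fit.to_json())
    report.standardized = fit.standardized
    report.equation = format_equation(fit, config.outcome)

    verdict = stage("characterize", characterize_model, fit, cohort, config)
    report.relevance = {
        "relevant": verdict.relevant,
        "threshold": verdict.threshold,
        "metrics": dataclasses.asdict(verdict.metrics),
    }
    report.incremental = stage(
        "incremental",
        incremental_inclusion,
        cohort,
        config.outcome,
        config.forced,
        consensus.retained,
    )
    rob = stage(
        "robustness",
        robustness_check,
        fit,
        cohort,
        rule=config.robustness,
        retention_fraction=config.robustness.get("retention_fraction", 0.5),
        relevance_threshold=config.r2_relevance if family == "linear" else config.c_relevance,
    )
    report.robustness = dataclasses.asdict(rob)

    if config.bootstrap_reps > 0:
        opt = stage(
            "optimism",
            bootstrap_optimism,
            cohort,
            config.outcome,
            config.forced,
            config.candidates,
            make_selection_pipeline(config),
            config.bootstrap_reps,
            seeds[1],
        )
        report.optimism = dataclasses.asdict(opt)

    ranges = {
        nm: (float(data[nm].min()), float(data[nm].max()))
        for nm in fit.names
    }
    table = stage("nomogram", build_nomogram, fit, ranges)
    report.nomogram = _nomogram_dict(table)
    return report


def render_report(report: RunReport, directory) -> dict:
    """Write report.json (full precision) and report.md; returns paths."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    json_path = directory / "report.json"
    json_path.write_text(report.to_json())

    lines = ["# Prediction-model run report", ""]
    lines.append(f"- outcome: `{report.config['outcome']}`  seed: {report.seed}")
    lines.append(f"- candidates screened: {len(report.screening)}")
    if report.validation["warnings"]:
        lines.append("- warnings: " + "; ".join(report.validation["warnings"]))
    lines.append("")
    if report.skip_reason:
        lines.append(f"**Run stopped early:** {report.skip_reason}")
    else:
        lines.append("## Final model")
        lines.append("")
        lines.append(f"`{report.equation}`")
        lines.append("")
        lines.append("## Standardized estimates")
        lines.append("")
        lines.append("| predictor | standardized estimate |")
        lines.append("|---|---|")
        for nm, v in report.standardized.items():
            lines.append(f"| {nm} | {v:.3f} |")
        lines.append("")
        m = report.relevance["metrics"]
        metric = m["r2_adj"] if m["family"] == "linear" else m["c_statistic"]
        name = "R2adj" if m["family"] == "linear" else "c-statistic"
        lines.append(
            f"Relevance: {name} = {metric:.3f} "
            f"({'relevant' if report.relevance['relevant'] else 'irrelevant'}, "
            f"threshold {report.relevance['threshold']})"
        )
        if report.robustness:
            r = report.robustness
            lines.append(
                f"Robustness: {name} {r['before']:.3f} -> {r['after']:.3f} after excluding "
                f"{r['n_excluded']} aberrant rows "
                f"({'robust' if r['robust'] else 'not robust'})"
            )
        if report.optimism:
            o = report.optimism
            lines.append(
                f"Optimism ({o['B']} bootstrap replicates): apparent {o['apparent']:.3f}, "
                f"optimism {o['optimism']:.3f}, corrected {o['corrected']:.3f}"
            )
        if report.nomogram:
            lines.append("")
            lines.append("## Nomogram")
            lines.append("")
            lines.append("| predictor | range | max points |")
            lines.append("|---|---|---|")
            for p in report.nomogram["predictors"]:
                lines.append(
                    f"| {p['name']} | [{p['range'][0]:.2f}, {p['range'][1]:.2f}] "
                    f"| {p['max_points']:.1f} |"
                )
    md_path = directory / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return {"json": str(json_path), "markdown": str(md_path)}
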