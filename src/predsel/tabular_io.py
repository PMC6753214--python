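"""Cohort tables, variable roles, run configuration and trial filter rules.

A cohort is one row per subject with a declared catalog of variables
(outcome / candidate / forced / arm / id).  Candidate covariates are the
kind of baseline instruments used in chronic-pain trials: pain intensity
(NRS-3), painDETECT total and symptom subscores, sleep quality, SF-12
summary scales, EQ-5D VAS, HADS anxiety/depression, global impressions of
change, demographics and vital signs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

ROLES = {"outcome", "candidate", "forced", "arm", "id"}
SCALES = {"continuous", "quasi_continuous", "binary", "ordinal"}

#: painDETECT total-score classification cutoffs from the instrument
#: literature: <= negative_max -> negative, <= unclear_max -> unclear,
#: above -> positive.
PDQ_CLASS_CUTOFFS = {"negative_max": 12, "unclear_max": 18}

TITRATION_LABELS = ("optimal_responder", "randomized", "non_responder")


class CohortError(ValueError):
    """Structural problem with a cohort table or its variable catalog."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort column."""

    name: str
    role: str
    scale: str = "continuous"
    units: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise CohortError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.scale not in SCALES:
            raise CohortError(f"unknown scale {self.scale!r} for variable {self.name!r}")


@dataclass
class Cohort:
    """Subject x variable table with a validated variable catalog.

    Values are numeric or missing (NaN); id and arm columns may hold
    strings.  Missingness is carried as-is — models drop incomplete rows
    per fit (complete-case analysis), never impute.
    """

    data: pd.DataFrame
    specs: list[VariableSpec]

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise CohortError("duplicate variable names in catalog")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise CohortError(f"cohort is missing declared column(s): {', '.join(missing)}")
        extra = [c for c in self.data.columns if c not in names]
        if extra:
            raise CohortError(f"cohort has undeclared column(s): {', '.join(extra)}")
        ids = [s for s in self.specs if s.role == "id"]
        if len(ids) != 1:
            raise CohortError(f"cohort must declare exactly one id variable, found {len(ids)}")
        idcol = self.data[ids[0].name]
        if idcol.duplicated().any():
            dup = idcol[idcol.duplicated()].iloc[0]
            raise CohortError(f"duplicate subject id {dup!r}")
        for s in self.specs:
            if s.scale == "binary" and s.role not in ("id", "arm"):
                vals = self.data[s.name].dropna().unique()
                if len(vals) > 2:
                    raise CohortError(
                        f"binary variable {s.name!r} takes {len(vals)} distinct values"
                    )

    # -- catalog access -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def id_var(self) -> str:
        return next(s.name for s in self.specs if s.role == "id")

    def spec_for(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise CohortError(f"no variable named {name!r} in catalog")

    def family_of(self, outcome: str) -> str:
        """Model family implied by the outcome scale (binary -> logistic)."""
        return "logistic" if self.spec_for(outcome).scale == "binary" else "linear"

    def names_with_role(self, role: str) -> list[str]:
        return [s.name for s in self.specs if s.role == role]

    def complete_cases(self, columns: list[str]) -> pd.DataFrame:
        """Rows with no missing value in any of `columns`."""
        return self.data.dropna(subset=list(columns))

    def subset(self, index) -> "Cohort":
        return Cohort(self.data.loc[index].copy(), list(self.specs))


def read_cohort(path, specs: list[VariableSpec]) -> Cohort:
    """Read a cohort CSV (comma separator, dot decimal, mandatory header).

    Numeric columns with unparsable entries get those cells set to missing
    and the offending (row, column) pairs recorded in ``cohort.parse_flags``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    declared = [s.name for s in specs]
    missing = [n for n in declared if n not in df.columns]
    if missing:
        raise CohortError(f"CSV is missing declared column(s): {', '.join(missing)}")
    flags = []
    out = {}
    for s in specs:
        col = df[s.name]
        if s.role in ("id", "arm"):
            out[s.name] = col
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna() & (col.str.strip() != "")
        if bad.any():
            if bad.all():
                # fully non-numeric column (e.g. a categorical label) kept as-is
                out[s.name] = col
                continue
            flags.extend((int(i), s.name) for i in np.flatnonzero(bad.to_numpy()))
        out[s.name] = numeric
    cohort = Cohort(pd.DataFrame(out)[declared], list(specs))
    cohort.parse_flags = flags
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write an RFC-4180-style CSV; missing values become empty fields."""
    cohort.data.to_csv(path, index=False, na_rep="")


def pdq_class_from_total(total: float, cutoffs: dict | None = None) -> str:
    """Classify a painDETECT total score as negative / unclear / positive."""
    c = cutoffs or PDQ_CLASS_CUTOFFS
    if np.isnan(total):
        raise ValueError("cannot classify missing PDQ total")
    if total <= c["negative_max"]:
        return "negative"
    if total <= c["unclear_max"]:
        return "unclear"
    return "positive"


def apply_inclusion_criteria(
    cohort: Cohort,
    age: str,
    duration_months: str,
    nrs3_baseline: str,
    pdq_class: str,
) -> tuple[Cohort, dict]:
    """Trial eligibility filter.

    Retains adults (age >= 18) with pain lasting >= 3 months, average pain
    intensity >= 6 on the NRS-3 at baseline, and an unclear or positive
    painDETECT classification.  A missing value in any criterion column
    excludes the row with reason ``missing``.  Returns the retained cohort
    and per-rule exclusion counts; counts plus retained rows add up to the
    input size.
    """
    for col in (age, duration_months, nrs3_baseline, pdq_class):
        if col not in cohort.data.columns:
            raise CohortError(f"criterion column {col!r} not in cohort")
    pclass = cohort.data[pdq_class]
    known = pclass.dropna().unique()
    bad = set(known) - {"negative", "unclear", "positive"}
    if bad:
        raise CohortError(f"unknown PDQ class value(s): {sorted(bad)}")

    counts = {"missing": 0, "age": 0, "duration": 0, "nrs3": 0, "pdq_class": 0, "retained": 0}
    keep = []
    for i, row in cohort.data.iterrows():
        vals = row[[age, duration_months, nrs3_baseline, pdq_class]]
        if vals.isna().any():
            counts["missing"] += 1
        elif row[age] < 18:
            counts["age"] += 1
        elif row[duration_months] < 3:
            counts["duration"] += 1
        elif row[nrs3_baseline] < 6:
            counts["nrs3"] += 1
        elif row[pdq_class] == "negative":
            counts["pdq_class"] += 1
        else:
            counts["retained"] += 1
            keep.append(i)
    return cohort.subset(keep), counts


def classify_titration_response(nrs3_baseline: float, nrs3_end: float) -> str:
    """Label the titration outcome from baseline and end-of-titration NRS-3.

    optimal_responder : end-of-titration pain below 4 (dramatic reduction;
        followed up open-label on the medium dose).
    randomized : at least a 1-point decrease with residual pain >= 4
        (mild response; enters the comparative period).
    non_responder : everything else.
    """
    for v in (nrs3_baseline, nrs3_end):
        if not (0 <= v <= 10):
            raise ValueError(f"NRS-3 score {v} outside [0, 10]")
    if nrs3_end < 4:
        return "optimal_responder"
    if nrs3_baseline - nrs3_end >= 1:
        return "randomized"
    return "non_responder"


@dataclass
class RunConfig:
    """Thresholds and settings for one pipeline run.

    weak/strong significance levels (0.05 / 0.001) drive the consensus
    rule; r2_relevance / c_relevance (0.3 / 0.6) mark models below them as
    irrelevant; variables_per_case is the events-per-variable guard (one
    variable per 20 cases).
    """

    outcome: str
    candidates: list[str]
    forced: list[str]
    screen_alpha: float = 0.05
    weak_alpha: float = 0.05
    strong_alpha: float = 0.001
    r2_relevance: float = 0.3
    c_relevance: float = 0.6
    variables_per_case: float = 1 / 20
    bootstrap_reps: int = 200
    seed: int = 0
    robustness: dict = field(
        default_factory=lambda: {
            "rule": "percentile_residual",
            "retention_fraction": 0.5,
            "prediction_percentiles": [5, 95],
            "residual_z": 2.5,
        }
    )

    def __post_init__(self):
        if not (0 < self.strong_alpha < self.weak_alpha < 1):
            raise ValueError("need 0 < strong_alpha < weak_alpha < 1")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if not (0 < self.variables_per_case <= 1):
            raise ValueError("variables_per_case must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def validate_cohort(cohort: Cohort, config: RunConfig) -> dict:
    """Structural checks and the one-variable-per-20-cases guard.

    Warns (never errors) when the candidate count exceeds
    n * variables_per_case, following the rule of thumb that a prediction
    model should use fewer than one variable per twenty cases.
    """
    if cohort.n == 0:
        raise CohortError("cohort has no rows")
    if config.outcome not in cohort.data.columns:
        raise CohortError(f"outcome column {config.outcome!r} not in cohort")
    warnings = []
    limit = cohort.n * config.variables_per_case
    if len(config.candidates) >= limit:
        warnings.append(
            f"{len(config.candidates)} candidates exceed the per-case guard "
            f"({cohort.n} cases allow at most {limit:.1f} variables)"
        )
    missingness = {
        s.name: int(cohort.data[s.name].isna().sum())
        for s in cohort.specs
        if s.role not in ("id", "arm")
    }
    return {"n": cohort.n, "warnings": warnings, "missingness": missingness}
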