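"""Synthetic trial cohorts with known ground truth.

Emulates the structure of a titration-then-randomization analgesic trial:
subjects enter a dose-titration phase; those with a dramatic pain
reduction (NRS-3 < 4) continue open-label as "optimal responders", those
with a mild response (>= 1-point decrease, residual pain >= 4) are
randomized to one of two comparative arms.  Candidate covariates are
correlated questionnaire scores (painDETECT family, HADS pair, SF-12
pair, vitals block) with sparse true effects on the outcome, so every
pipeline stage can be exercised against a known support.

Covariates are drawn as unit-variance Gaussians (optionally discretized
to instrument ranges by rank-preserving rounding); effects are therefore
standardized coefficients, and the default noise scale normalizes the
outcome to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tabular_io import Cohort, VariableSpec, classify_titration_response

#: The default 46-candidate catalog: named clinical instruments plus
#: generic clinical-history fillers.
INSTRUMENTS = [
    "NRS3", "PDQ_total", "PDQ_burning", "PDQ_paresthesia", "PDQ_allodynia",
    "PDQ_attacks", "PDQ_thermal", "PDQ_numbness", "PDQ_pressure", "SQ",
    "SF12_MCS", "SF12_PCS", "EQ5D_VAS", "HADS_A", "HADS_D", "PGIC", "CGIC",
    "age", "BMI", "weight", "height", "heart_rate", "systolic_bp", "diastolic_bp",
]

#: Instrument score ranges used when discretizing (lo, hi).
INSTRUMENT_RANGES = {
    "NRS3": (0, 10), "PDQ_total": (0, 38), "PDQ_burning": (0, 5),
    "PDQ_paresthesia": (0, 5), "PDQ_allodynia": (0, 5), "PDQ_attacks": (0, 5),
    "PDQ_thermal": (0, 5), "PDQ_numbness": (0, 5), "PDQ_pressure": (0, 5),
    "SQ": (0, 100), "SF12_MCS": (10, 70), "SF12_PCS": (10, 70),
    "EQ5D_VAS": (0, 100), "HADS_A": (0, 21), "HADS_D": (0, 21),
    "PGIC": (1, 7), "CGIC": (1, 7), "age": (18, 85), "BMI": (17, 45),
    "weight": (45, 140), "height": (150, 200), "heart_rate": (50, 110),
    "systolic_bp": (90, 180), "diastolic_bp": (55, 110),
}

#: Correlated questionnaire blocks (members, common within-block r).
DEFAULT_BLOCKS = [
    (["PDQ_total", "PDQ_burning", "PDQ_paresthesia", "PDQ_allodynia",
      "PDQ_attacks", "PDQ_thermal", "PDQ_numbness", "PDQ_pressure"], 0.55),
    (["HADS_A", "HADS_D"], 0.5),
    (["SF12_MCS", "SF12_PCS"], 0.25),
    (["heart_rate", "systolic_bp", "diastolic_bp"], 0.4),
    (["weight", "height", "BMI"], 0.5),
]

#: Sparse true effects mirroring a plausible pain-trial signal: outcome
#: improves with mental health and neuropathic-component scores, worsens
#: with depression, poor sleep and high baseline pain.
DEFAULT_EFFECTS = {
    "SF12_MCS": -0.35,
    "PDQ_total": 0.30,
    "HADS_D": -0.30,
    "SQ": 0.25,
    "NRS3": -0.20,
}


def candidate_names(count: int = 46) -> list[str]:
    names = list(INSTRUMENTS)
    i = 1
    while len(names) < count:
        names.append(f"clin_{i:02d}")
        i += 1
    return names[:count]


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 261 randomized subjects, 46 candidates."""

    n: int = 261
    n_candidates: int = 46
    correlation: tuple = ("block", None)   # ("block", blocks) | ("exchangeable", rho)
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baseline_effect: float = -0.30         # pull of the baseline outcome value
    outcome: str = "MCS_response"
    family: str = "linear"
    noise_sd: float | None = None          # None -> normalize Var(outcome) to 1
    arm_fractions: tuple[float, float] = (127 / 261, 134 / 261)
    titration_baseline: tuple[float, float] = (7.2, 0.8)   # mean, sd on [6, 10]
    titration_shift: tuple[float, float] = (1.8, 1.5)      # mean, sd of the NRS drop
    discretize: bool = False
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        names = candidate_names(self.n_candidates)
        p = len(names)
        R = np.eye(p)
        kind, param = self.correlation
        if kind == "exchangeable":
            rho = param or 0.0
            R[:] = rho
            np.fill_diagonal(R, 1.0)
        elif kind == "block":
            blocks = param if param is not None else DEFAULT_BLOCKS
            idx = {nm: i for i, nm in enumerate(names)}
            for members, rho in blocks:
                present = [idx[m] for m in members if m in idx]
                for a in present:
                    for b in present:
                        if a != b:
                            R[a, b] = rho
        else:
            raise ValueError(f"unknown correlation structure {kind!r}")
        # positive-definiteness check doubles as the error contract
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        return R

    def design_r2(self) -> float:
        """Outcome variance share explained by the true effects (+ baseline)."""
        names = candidate_names(self.n_candidates)
        beta = np.array([self.effects.get(nm, 0.0) for nm in names])
        R = self.correlation_matrix()
        signal = float(beta @ R @ beta) + self.baseline_effect**2
        sigma2 = self.noise_sd**2 if self.noise_sd is not None else max(1.0 - signal, 1e-12)
        return signal / (signal + sigma2)


def _norm_cdf(z):
    from scipy.special import ndtr

    return ndtr(z)


def simulate_cohort(config: SyntheticConfig) -> tuple[Cohort, dict]:
    """Draw one cohort plus its ground-truth record.

    The ground truth lists exactly the covariates with nonzero effect,
    their coefficients, the intercept, the realized noise SD and the
    design R².
    """
    rng = np.random.default_rng(config.seed)
    names = candidate_names(config.n_candidates)
    unknown = set(config.effects) - set(names)
    if unknown:
        raise ValueError(f"effects refer to unknown candidates: {sorted(unknown)}")
    R = config.correlation_matrix()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((config.n, len(names))) @ L.T
    baseline_name = f"{config.outcome}_baseline"
    pre = rng.standard_normal(config.n)

    beta = np.array([config.effects.get(nm, 0.0) for nm in names])
    signal_var = float(beta @ R @ beta) + config.baseline_effect**2
    if config.noise_sd is None:
        noise_sd = float(np.sqrt(max(1.0 - signal_var, 1e-12)))
    else:
        noise_sd = config.noise_sd
    lp = Z @ beta + config.baseline_effect * pre
    if config.family == "linear":
        y = lp + noise_sd * rng.standard_normal(config.n)
        outcome_scale = "continuous"
    elif config.family == "logistic":
        prob = 1.0 / (1.0 + np.exp(-lp / max(noise_sd, 1e-12)))
        y = rng.binomial(1, prob).astype(float)
        outcome_scale = "binary"
    else:
        raise ValueError(f"unknown family {config.family!r}")

    # titration phase on the 0-10 pain scale; baseline rank-linked to NRS3
    nrs_idx = names.index("NRS3") if "NRS3" in names else None
    z_nrs = Z[:, nrs_idx] if nrs_idx is not None else rng.standard_normal(config.n)
    mu, sd = config.titration_baseline
    tit_base = np.clip(mu + sd * z_nrs, 6.0, 10.0)
    shift = rng.normal(*config.titration_shift, size=config.n)
    tit_end = np.clip(tit_base - shift, 0.0, 10.0)
    labels = [classify_titration_response(b, e) for b, e in zip(tit_base, tit_end)]

    arms = np.array(["open_label"] * config.n, dtype=object)
    randomized = [i for i, lab in enumerate(labels) if lab == "randomized"]
    f_mono = config.arm_fractions[0] / sum(config.arm_fractions)
    pick = rng.random(len(randomized)) < f_mono
    for i, mono in zip(randomized, pick):
        arms[i] = "TapMono" if mono else "TapPre"
    arms[[i for i, lab in enumerate(labels) if lab == "non_responder"]] = "discontinued"

    X = pd.DataFrame(Z, columns=names)
    if config.discretize:
        for nm in names:
            lo, hi = INSTRUMENT_RANGES.get(nm, (0, 100))
            X[nm] = np.round(lo + (hi - lo) * _norm_cdf(X[nm]))

    df = pd.DataFrame({"subject_id": [f"S{i + 1:04d}" for i in range(config.n)]})
    df["arm"] = arms
    df[baseline_name] = pre
    df[config.outcome] = y
    df = pd.concat([df, X], axis=1)
    df["nrs3_titration_baseline"] = tit_base
    df["nrs3_titration_end"] = tit_end
    df["titration_label"] = pd.Series(labels, dtype=object).map(
        {"optimal_responder": 1.0, "randomized": 0.0, "non_responder": 0.0}
    )

    specs = (
        [
            VariableSpec("subject_id", "id"),
            VariableSpec("arm", "arm"),
            VariableSpec(baseline_name, "forced"),
            VariableSpec(config.outcome, "outcome", scale=outcome_scale),
        ]
        + [VariableSpec(nm, "candidate", scale="quasi_continuous") for nm in names]
        + [
            VariableSpec("nrs3_titration_baseline", "candidate", scale="quasi_continuous"),
            VariableSpec("nrs3_titration_end", "candidate", scale="quasi_continuous"),
            VariableSpec("titration_label", "outcome", scale="binary"),
        ]
    )
    cohort = Cohort(df, specs)
    truth = {
        "support": sorted(nm for nm, b in config.effects.items() if b != 0),
        "coefficients": {nm: float(b) for nm, b in config.effects.items() if b != 0},
        "baseline_effect": config.baseline_effect,
        "intercept": 0.0,
        "noise_sd": noise_sd,
        "design_r2": config.design_r2(),
        "outcome": config.outcome,
        "baseline_name": baseline_name,
        "seed": config.seed,
    }
    return cohort, truth


def make_null_cohort(n: int, candidate_count: int = 46, seed: int = 0) -> Cohort:
    """Cohort whose candidates are all independent of the outcome.

    Used by the type-I-error and optimism suites: any candidate the
    pipeline retains here is a false positive.
    """
    if n < 10:
        raise ValueError("null cohort needs n >= 10")
    config = SyntheticConfig(
        n=n,
        n_candidates=candidate_count,
        correlation=("exchangeable", 0.0),
        effects={},
        baseline_effect=0.0,
        seed=seed,
    )
    cohort, _ = simulate_cohort(config)
    return cohort
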