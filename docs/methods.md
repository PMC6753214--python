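# Methods

`predsel` implements a staged procedure for building and internally
validating clinical prediction models when the candidate covariate list is
large relative to the number of cases — the typical situation in post hoc
analyses of randomized analgesic trials, where dozens of questionnaire
scores (pain intensity, painDETECT, sleep, SF-12, EQ-5D, HADS, global
impressions) and demographics are available for only one or two hundred
subjects. A model should use fewer than one variable per twenty cases;
the pipeline starts from the full candidate list anyway and relies on the
stages below to control the resulting optimism.

## The staged procedure

**Stage 1 — bivariable screening.** Each candidate is tested in a model
of the outcome containing only the baseline value of that outcome and the
candidate (linear regression for continuous or quasi-continuous outcomes,
logistic for binary ones). Candidates with a Wald p-value below
`screen_alpha` (default 0.05) survive. Forcing the baseline in means a
candidate must carry information beyond where the subject started. In
parallel each candidate/outcome relationship is mapped — Pearson r,
Spearman ρ, and the p-value of a quadratic term in `y ~ x + x²` — and
flagged as *monotone nonlinear* (|ρ| − |r| > 0.1) or *non-monotone*
(quadratic p < 0.05 and |ρ| < 0.3). Flags are advisory, recorded in the
report; they never remove a candidate automatically.

**Stage 2 — collinearity reduction by factor analysis.** Principal
components of the screened candidates' correlation matrix are extracted
and varimax-rotated; a candidate joins the factor on which its absolute
loading is largest when that loading reaches `loading_threshold`
(default 0.6), and each group keeps only the member with the largest
absolute loading (ties broken by smaller screening p-value, then name).
The factor count is chosen by Bartlett's sequential eigenvalue-equality
test at α = 0.05 rather than the Kaiser eigenvalue-greater-than-one rule
(both are available): on sample correlation matrices of weakly correlated
candidates the Kaiser rule retains pure-noise factors whose rotated
loadings routinely exceed 0.6, which makes the stage group *independent*
variables and discard genuine predictors. Bartlett's test retains a
factor only while the remaining eigenvalues differ more than sampling
spread allows, so an identity-like matrix yields no factors and every
candidate stays a singleton. Parallel analysis would serve the same
purpose but is deliberately out of scope.

**Stage 3 — consensus selection.** Three selection processes run on the
reduced set with the baseline outcome forced into every model:

- *forward*: add the candidate with the smallest nested-test p-value
  (F-change for linear, likelihood-ratio for logistic) while it is below
  `entry_alpha` (0.05);
- *backward*: from the full model, drop the non-forced covariate with the
  largest Wald p ≥ `stay_alpha` (0.05);
- *Lasso* (linear outcomes only): forced covariates are partialled out
  (Frisch–Waugh), candidates standardized, and the L1 penalty chosen by
  seeded 10-fold cross-validation; because the Lasso yields no p-values,
  significance is taken from an unpenalized refit on the selected set.

A predictor is retained when it is at least weakly significant
(p < 0.05) in two of the three processes *and* highly significant
(p < 0.001) in at least one. Binary outcomes have only two applicable
processes, so the rule tightens to 2-of-2 weak plus one strong.

**Stage 4 — characterization and validation.** The final model (forced +
consensus set) is characterized by adjusted R² (linear) or the
c-statistic (logistic); values below 0.3 / 0.6 mark the model irrelevant.
Covariates are re-entered one at a time in order of decreasing absolute
standardized estimate, reporting the nested-test p-value at each step.
Robustness excludes rows in aberrant ranges of the model function —
predictions outside the [5th, 95th] percentile or absolute standardized
residuals above 2.5 — refits, and calls the model robust when the metric
keeps at least `retention_fraction` (0.5) of its value and stays above
the relevance threshold. Optimism is estimated by re-running the
*entire* stage 1–3 procedure on each of B bootstrap resamples (default
200), scoring each resample-built model on its own resample (apparent)
and on the original cohort (test); `optimism = mean(apparent − test)` and
the corrected metric is `apparent_original − optimism`. Replicates whose
consensus is empty fall back to the forced-only model; logistic
resamples missing an outcome class are skipped and counted.

**Nomogram.** Each covariate's influence is |coefficient| × range; the
largest influence spans 0–100 points and every other axis is scaled
proportionally, with the zero-point end at the covariate value minimizing
its contribution. All maps are affine, so summing points and reading off
the response is algebraically identical to evaluating the equation; the
package tests this identity exactly. Ranges default to the cohort's
observed min/max and can be overridden with instrument ranges (0–10 for
the pain NRS, 0–38 for painDETECT, 0–21 for HADS subscales, …).

## Numerical choices

- Linear Wald p-values use the t distribution (small-sample correct);
  logistic ones the normal approximation. Logistic fits iterate Newton
  steps to a 1e-8 parameter tolerance (max 100 iterations); separation is
  flagged when a standardized coefficient magnitude exceeds 15.
- Missing data: complete-case per fitted model; nothing is imputed.
- The c-statistic counts tied score pairs as 1/2 (trapezoidal ROC area).
- Rank deficiency is detected by pivoted QR and reported with the names
  of the dependent columns.
- F-change and likelihood-ratio statistics are clipped at zero;
  zero-degree-of-freedom comparisons return p = 1.
- One run seed fans out through spawned substreams to the selection,
  bootstrap and robustness stages, so changing B never perturbs the
  selected model and identical seeds give byte-identical reports.

## The synthetic cohort generator

Because the motivating trial data are available only on request, the
generator emulates the study design: a titration phase on the 0–10 pain
scale (baseline centered at 7.2 within the eligible [6, 10] range, a
treatment shift of mean 1.8, SD 1.5) whose outcome labels subjects as
*optimal responders* (end-of-titration pain < 4, continued open-label),
*randomized* (≥ 1-point decrease with residual pain ≥ 4, split ~127:134
between a monotherapy and a combination arm) or *non-responders*. The 46
candidates are unit-variance Gaussians with a block correlation
structure (painDETECT family at r = 0.55, HADS pair at 0.5, SF-12 pair at
0.25, vitals at 0.4, anthropometrics at 0.5); the outcome is a sparse
linear (or logistic) signal — by default five instruments with
standardized effects 0.2–0.35 plus a baseline-outcome pull of −0.3 — with
noise scaled so the outcome has unit variance, making effects directly
standardized coefficients and the design R² available in closed form.
Scores can optionally be discretized to instrument ranges by
rank-preserving rounding; the continuous form is the default so that the
calibration checks (empirical correlations and realized R² within ±0.05
of their design values at n = 5000) are exact.

What passing tests on these cohorts shows: the pipeline's type-I error,
recovery and optimism behavior under known sparse truth at the study's
scale. What it does not show: behavior under real questionnaire
pathologies — floor/ceiling effects, informative missingness, ordinal
coarseness, non-Gaussian tails — none of which the generator emulates.

The dedicated property suites use scenarios chosen once: the null suite
draws 46 candidates independent of the outcome (n = 260, 200
replicates); the recovery suite places standardized effects of 0.3 on
five *mutually independent* candidates (n = 260, 100 replicates) so that
it measures selection power rather than which member of a correlated
block happens to represent its factor; the optimism suite uses a fixed
single-predictor model at n = 2000 (B = 100) and full in-bootstrap
reselection over 40 noise candidates at n = 100 (B = 200).

## Known limitations

- Stepwise entry/stay thresholds, the loading threshold, the bootstrap
  replicate count and the "considerable decrease" retention fraction are
  conventions, not estimates; all are configurable and echoed into the
  run report.
- The robustness rule always trims the prediction tails (10% of rows by
  default), so even clean data shows a small range-restriction drop in
  the refitted metric; the robust/not-robust verdict accounts for this
  via the retention fraction.
- The Lasso process applies to linear outcomes only; binary pipelines
  use the two-process consensus rule.
- With strongly correlated true predictors, the factor stage keeps one
  representative per cluster by design — "recovery" of every individual
  cluster member is not a goal of the method.
- No imputation, no interaction terms, no splines for flagged nonlinear
  relationships, no survival or mixed models.
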