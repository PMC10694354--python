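# Methods

## The time-to-alteration endpoint

A patient's longitudinal toxicity record is reduced to a single survival
time in three stages.

**Per-indicator trajectory fits.** For each patient and each continuous
indicator, value is regressed on time (years from randomization) by ordinary
least squares using all available visits; missing intermediate visits simply
contribute nothing (no imputation). The slope's two-sided t-test p-value is
undefined with only two points, in which case the series can never count as
a significant decline. The continuous composite components are the derived
series FEV1/FVC, DLCO/VA (per-visit ratios, matched by visit time; visits
missing either member or with a zero denominator are dropped with a logged
warning), TLC, and LVEF. RV is excluded from the default composite; a user
overriding the indicator set should supply it as RVinv = −log RV so that
decline means deterioration.

**Threshold crossing and censoring.** With baseline *y₀* (the observed t=0
value; the fitted intercept is the fallback anchor when the baseline visit is
missing) and threshold fraction *d*, the candidate event time solves
*a + b t\** = (1−d) *y₀*. A patient is censored at their actual follow-up
time when the fit shows no significant decline (slope ≥ 0 or slope p ≥
α_slope) or when *t\** exceeds follow-up. A negative *t\** — the fitted line
already below threshold at t=0, possible with a noisy baseline — is recorded
as an event at time 0, the earliest admissible event time. A perfectly
collinear decline (residual SD 0 with ≥3 points) is treated as significant
even where floating-point noise makes the textbook p-value degenerate.

**Composite first event.** The composite event time is the minimum over the
four component families: lung TTA, heart TTA, first RTOG grade increase
above baseline (lung or heart), and first fatigue/dyspnea increase above
baseline. Ties are labelled by the fixed precedence lung → heart → RTOG →
fatigue-dyspnea; the time itself is unaffected. Patients with no component
event are censored at follow-up, so every randomized patient appears exactly
once in the event table (strict intention-to-treat).

Key tunables (all in `AnalysisConfig`): `d` (default 0.10; sweep default
{0.10, 0.20, 0.40, 0.60}), `alpha_slope` (default 0.05 — the significance
criterion for "decline" is a genuine analysis choice, exposed rather than
hard-wired), `pro_rule` (`"category"`: a fatigue/dyspnea event is a
mild→moderate→severe category increase; `"raw"` uses any raw-score increase),
`rmst_tau` (default: the largest horizon observable in both arms),
`age_cut` (50 years) for subgroup dichotomization.

## Grading

Continuous indicators are graded 0–4 relative to baseline with CTCAE-adapted
cutoffs: percent decline in (10,25] → 1, (25,50] → 2, (50,75] → 3, >75 → 4
for pulmonary tests; absolute percentage-point drops with bounds 10/20/30/50
for LVEF (a relative variant is available for sensitivity). All intervals
are left-open right-closed; a decline of exactly 10% is grade 0, and any
improvement is grade 0 — only deterioration is graded. Raw 1–4 QLQ symptom
scores map linearly to 0–100 (`100·(raw−1)/3`) and categorize as mild
[0,20], moderate (20,40], severe >40. RTOG grades pass through unchanged.
The grade table (counts and column-wise percentages per indicator × grade,
split at 5 years of follow-up and by arm) is descriptive only; no
proportion tests are attached to it. Because RVinv = −log RV is negative for
RV > 1 L, percent change is ill-defined on it; the tabulated RVinv grades
are computed from the percent *increase* of raw RV with the same cutoffs,
which preserves the deterioration direction.

## Survival inference

Kaplan–Meier estimation, the two-group log-rank test and Cox regression are
delegated to lifelines (Newton tolerance tightened to 1e-9 so small-sample
fits agree with a direct partial-likelihood maximization to ~1e-7). Cox
models use Efron tie handling throughout: event times concentrate on the
yearly visit grid, so ties are heavy. RMST is computed by exact rectangle
integration of the KM step function — the curve is piecewise constant, so
adaptive quadrature is both slower and less exact — with the standard
asymptotic variance Σⱼ Aⱼ² dⱼ/(nⱼ(nⱼ−dⱼ)) over event times (Aⱼ the area
under S from tⱼ to τ); values and standard errors match R `survival`'s
`summary(survfit, rmean=τ)` to printed precision. The RMST difference uses a
two-sided normal test on Δ = RMST₁ − RMST₀. The default horizon τ is the
minimum across arms of the largest observed time, the largest τ at which
both curves are identified. Subgroup scans fit the arm effect separately in
each covariate level and test arm × covariate interaction by a joint Wald
test on the interaction block; continuous age is dichotomized at 50 years,
weight at its cohort median; levels without events, single-level covariates,
and non-converging interaction models are skipped with logged warnings
rather than aborting the scan. Overall survival takes death from any cause
as the event; disease-free survival the earliest of death or recurrence.

## The synthetic cohort generator

The generator emulates the measurement design the analysis assumes — it is a
test bed, not a disease model. Visits fall at 0, 0.25 y (a single
deterministic point for the "1–3 months after therapy" window: the midpoint
of 1–3 months after a 3–7-week course) and then yearly. Continuous
indicators follow patient-specific lines: baseline drawn from the published
per-arm baseline means/SDs (e.g. control FEV1 2.44 L, SD 0.56; LVEF 62.6%,
SD 4.5), plus an arm-specific linear slope, plus i.i.d. Gaussian measurement
error (~5% of baseline, a test-retest magnitude), floored at 1% of the
baseline mean to respect positivity. A linear truth model is deliberate:
the TTA estimator itself fits a line, so parameter-recovery tests compare
like with like. RTOG grades are a monotone step process with a yearly
one-grade transition probability; raw QLQ scores drift upward linearly and
are clipped to [1,4]. Death, dropout and recurrence are independent
exponentials — the simplest model that exercises every censoring branch —
and follow-up is min(13 y, dropout, death). Strata (nodal status, surgery,
chemotherapy sequence) are independent Bernoulli/categorical draws at the
published cohort frequencies, and arms are assigned by Efron's biased coin
(p_bias = 2/3) independently per stratum combination.

The source study does not report per-arm trajectory slopes, so the decline
rates are free parameters, fixed once: control-arm slopes of roughly
0.4–2.3% of baseline per year per indicator with experimental-arm rates at
~60% of control, RTOG transition 0.05 vs 0.03 /y, QLQ drift 0.04 vs
0.025 /y. These plant a real arm effect of plausible magnitude. What passing
tests show is therefore that the *pipeline* detects a planted effect with
the right direction and operating characteristics — not that any particular
hazard ratio generalizes to real patients. Features of real data the
generator does not emulate: nonlinear or step-change trajectories (a config
switch could add them), informative censoring, within-patient correlation
across indicators beyond the shared arm effect, visit-time jitter, and
missing single visits.

## Design choices and numerical notes

- **Sample size.** The Fleiss continuity correction is the default because
  it is the variant that yields 118 total for the 25%→5% design (the
  uncorrected pooled-variance formula gives 98); both are exposed, and the
  CLI prints both.
- **Efron's coin** defaults to p_bias = 2/3, the classical value; the
  imbalance within a stratum is a random walk with restoring drift — bounded
  in distribution, not bounded by 1 — and the tests check exactly that.
- **Ceil with epsilon.** Sample sizes take `ceil(n − 1e-12)` so that values
  computed exactly at an integer are not bumped up by floating-point dust.
- **Determinism.** The simulator is a pure function of (config, seed); the
  pipeline is a pure function of (config, inputs). Report TSVs are
  byte-identical across runs.
- **Validation at the boundary.** CSV readers reject, and log with line
  numbers, rows with unknown indicator codes, negative times, non-positive
  continuous values, non-integer or out-of-range RTOG grades, raw QLQ values
  outside [1,4], duplicate visit times, and non-positive follow-up.
- **Degenerate inputs.** All-censored tables give an empty KM curve (S ≡ 1)
  and RMST = τ; a zero-dynamics cohort yields zero composite events and
  RMST = τ in both arms; empty grade input yields an empty table; log-rank
  and Cox refuse event-free tables rather than returning NaNs.

## Problem sizes

Default test and acceptance runs use cohorts of 20–120 patients (5000/arm
only for a baseline-mean CLT check with follow-up shortened to 0.5 y), 1000
replicates of n = 1000 for the log-rank type-I error rate, and n = 2000 for
Cox effect recovery — sizes at which the Monte-Carlo error of each check is
comfortably below its assertion margin.

## Known limitations

The TTA depends on the chosen indicator set, the regression family, and the
threshold d; the sweep quantifies only the last. No joint
longitudinal–survival model is fitted, components are unweighted, and no
competing-risks treatment of death is attempted (death censors the
composite). The per-patient OLS ignores measurement-error autocorrelation.
Category-based PRO events can trigger on measurement noise near a category
boundary; the `raw` rule is noisier still. The published trial's exact
effect estimates are reproducible only from its deposited dataset, which
this package treats as an optional ingestion target, not a dependency.
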