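# ttakit

Composite **time-to-alteration (TTA)** analysis of lung–heart toxicity for
two-arm randomized radiotherapy trials.

Late cardiopulmonary toxicity after breast radiotherapy is multi-dimensional:
pulmonary function tests (FEV1, FVC, DLCO, VA, RV, TLC), echocardiographic
left ventricular ejection fraction (LVEF), clinician-assigned RTOG late
morbidity grades, and patient-reported fatigue/dyspnea (EORTC QLQ-C30) each
tell part of the story, and tabulating ordinal grades per indicator is hard
to interpret and wasteful of longitudinal information. The TTA endpoint
condenses all of it into a single per-patient survival time: *how long does a
patient stay free of a d% deterioration in any lung or heart measure?*
`ttakit` is aimed at trial statisticians and methods researchers who want to
apply or study this endpoint, with a synthetic trial generator so the whole
pipeline is exercisable without patient data.

## The statistic

For patient *i* and continuous indicator *k* with measurements
*y<sub>ikj</sub>* at times *t<sub>ij</sub>* (years from randomization), an
ordinary least-squares line *y = a + b t* is fitted per patient and
indicator. With baseline value *y<sub>ik0</sub>* and deterioration fraction
*d* (default 0.10), the crossing time solves

&nbsp;&nbsp;&nbsp;&nbsp;*a + b t\* = (1 − d) · y<sub>ik0</sub>*

If the regression shows no significant decline (*b* ≥ 0, or the two-sided
slope p-value ≥ α<sub>slope</sub> = 0.05), or *t\** exceeds the patient's
follow-up, the patient is censored for that indicator at their actual
follow-up time. Ordinal indicators (RTOG grades; fatigue/dyspnea categorized
mild/moderate/severe on the 0–100 scale) contribute an event at the first
visit whose grade exceeds baseline. The **composite event** is the first
occurrence of any of: lung TTA (FEV1/FVC, DLCO/VA, TLC), heart TTA (LVEF),
RTOG grade increase, or fatigue-dyspnea increase. The composite is analyzed
by Kaplan–Meier, the log-rank test, restricted mean survival time (RMST) at
a horizon τ, and Cox regression (Efron ties) with subgroup interaction
scans — all by intention-to-treat.

The package also provides the trial-design pieces (continuity-corrected
two-proportion sample size; Efron's biased-coin stratified randomization),
CTCAE-adapted ordinal grading with a descriptive grade table, and a
sensitivity sweep of the whole analysis over d ∈ {10%, 20%, 40%, 60%}.

## Worked example

Simulate a 120-patient two-arm trial in which the control arm ("CRT")
declines faster than the experimental arm ("H-IGRT"), then run the full
analysis:

```sh
$ ttakit simulate --n-per-arm 60 --seed 1 --outdir demo
wrote demo/patients.csv (120 patients)
wrote demo/measurements.csv (16005 measurements)

$ ttakit analyze --patients demo/patients.csv --measurements demo/measurements.csv --outdir demo/report
log-rank p=1.903e-05; RMST diff=1.47 y (tau=6.33); HR=0.413 [0.271, 0.632]
report written to demo/report/
```

Read: the arms' composite event-free curves differ strongly (log-rank
p ≈ 2·10⁻⁵); over the first 6.33 years (the common observable horizon) the
experimental arm stays free of a 10% lung-heart deterioration 1.47 years
longer on average; its hazard of deterioration is 0.41 times the control
arm's (95% CI 0.27–0.63). `demo/report/` holds the grade table, per-patient
TTA components, composite events, KM curves, endpoint and subgroup summaries,
the threshold sweep, and the run log as TSV.

The same library calls are available in Python:

```python
from ttakit import SimConfig, simulate_cohort, AnalysisConfig, run_pipeline

patients, measurements = simulate_cohort(SimConfig(n_per_arm=60, seed=1))
bundle = run_pipeline(AnalysisConfig(), patients, measurements)
bundle["summary"]["hr"]          # 0.413...
```

Design computations:

```sh
$ ttakit sample-size
 p_control  p_experimental  power  n_per_arm  n_total  n_per_arm_uncorrected  n_total_uncorrected
      0.25            0.05    0.8         59      118                     49                   98
```

i.e. detecting a reduction of any-grade toxicity from 25% to 5% at two-sided
α = 0.05 and power 0.80 requires 59 patients per arm (118 total) with the
Fleiss continuity correction.

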