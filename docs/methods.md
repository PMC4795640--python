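# Methods

## The score and its banding

The Modified Early Warning Score sums five integer subscores: systolic
blood pressure (0–3), pulse rate (0–3), respiratory rate (0–3), axillary
temperature (0 or 2 — the temperature row has no 1-band), and AVPU
consciousness (Alert 0, Voice 1, Pain 2, Unresponsive 3). The maximum
attainable total is 14. A single observation set per patient is scored; no
trend or longitudinal scoring is attempted, and diastolic pressure and
SpO2 are carried through the pipeline but never scored.

The published band table is stated over integer-looking ranges
("41–50", "101–199", "35–38.4") that leave the boundaries between bands
formally unassigned for real-valued measurements. This package closes
every such gap with one uniform convention: **each band extends down to
the printed start of the band below it**, i.e. the rule is a set of
half-open intervals `[lo, hi)` cut at the printed lower bounds, with each
parameter's top band closed at the admissible-range ceiling. Concretely:
SBP < 71 scores 3 and SBP >= 200 scores 2; pulse <= 40 scores 2 and
>= 130 scores 3; respiratory rate <= 8 scores 2 and >= 30 scores 3;
temperature below 35.0 scores 2, [35.0, 38.5) scores 0, and >= 38.5
scores 2. Exhaustiveness (every admissible value maps to exactly one
subscore) is enforced at band-construction time and re-verified by a
0.1-step scan in the tests. Whether a value such as 38.45 °C "should"
score 0 or 2 is not decidable from the printed rule; the convention here
is declared, kept entirely inside `ScoreBands`, and alternatives are one
YAML file away. Measurements are scored as given — no rounding is imposed
before band lookup.

Admissible ranges (SBP 1–300 mmHg, pulse 1–250 bpm, RR 1–80 /min,
temperature 25–45 °C) bound both input validation and the truncation of
unbounded printed bands; values outside them are rejected naming the
parameter rather than clamped.

Missing scored vitals reject the record (listing the missing fields)
rather than imputing — the same exclusion rule the study design applies.

## Prognostic indicators

All cutoff indicators derive from the 2x2 table of (MEWS >= c) against
death in hospital by day 7. Patients discharged before day 7 and patients
still on the ward both count as alive; self-discharged patients are
excluded before table construction (their counts are logged). Formulas:

- sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp);
  zero denominators raise an explicit error rather than returning 0.
- LR+ = sens/(1−spec), CI by the log method:
  `exp(ln LR+ ± z·sqrt(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)))`. With a
  zero cell the point is returned (when defined) and the CI is NaN.
- NNE = 1/PPV.
- OR = tp·tn/(fp·fn), Wald CI `exp(ln OR ± z·sqrt(Σ 1/cell))`, two-sided
  p from the Wald z. Any zero cell triggers the Haldane–Anscombe +0.5
  correction, flagged in the result. No other continuity correction, and
  no multiple-testing adjustment anywhere (single-test p < 0.05
  convention).
- AUROC of the binary flag is the single-operating-point trapezoid
  (sens+spec)/2, with a Hanley–McNeil standard error; AUROC of a graded
  score is Mann–Whitney U/(n1·n0) with ties counted 1/2. The two coincide
  exactly on 0/1 scores, which the tests assert.

Internal computation is full precision; rounding (proportions to four
decimals, ratios to two) happens only in the report layer.

Group comparisons (e.g. analyzed vs. self-discharged) use the two-sample
pooled t-test for continuous features and the chi-square test for
categorical ones, switching automatically to Fisher's exact test when any
expected cell count is below 5 (for 2x2 layouts; larger sparse tables are
flagged). Constant features are skipped with a note.

## Logistic regression

Maximum likelihood via iteratively reweighted least squares (statsmodels
GLM, binomial family), convergence when successive log-likelihoods change
by < 1e-8, at most 100 iterations; both limits are arguments. Categorical
covariates enter as indicators against a declared reference level;
continuous covariates enter untransformed per unit. Missingness is
handled complete-case per model with the exclusion count reported on the
fit (relevant mainly for HIV status, unrecorded in a quarter of
patients). Singular designs are rejected naming the collinear columns.
Quasi-separation — any fitted probability within 1e-10 of 0 or 1 together
with a coefficient magnitude above 12 — flags the fit as non-converged
rather than silently returning a diverged estimate.

Backward elimination refits after removing the term with the largest
joint Wald p at or above alpha (default 0.05) until all remaining terms
pass. Wald rather than likelihood-ratio p-values drive removal, matching
the Wald intervals used throughout. Multi-column categorical terms are
tested jointly. Exact p ties are broken by declared predictor order, the
later-declared term leaving first, which makes the procedure
deterministic for a given spec; the final term *set* is order-invariant
except at exact ties.

Goodness of fit pools observations by distinct covariate pattern and
compares the grouped deviance to chi-square with (patterns − parameters)
degrees of freedom; the raw individual-level residual deviance is carried
alongside, since its reference distribution is unreliable for sparse
binary data. df <= 0 (e.g. a saturated pattern set) is reported as
undefined rather than a p-value.

## The synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not ward
physiology. Per patient, independently given the seed:

- MEWS total from an explicit mass on 0–9:
  (.12, .22, .24, .208, .095, .055, .03, .016, .01, .006) — median 2,
  IQR 1–3, P(>=4) = 0.212, P(>=5) = 0.117. These are stored constants,
  chosen once to satisfy the published summary statistics; the full
  histogram behind them was never published numerically, so this is a
  calibrated stand-in, not a reconstruction.
- Vitals by inversion: a subscore composition achievable under the band
  rule is drawn uniformly among compositions with the requested sum, then
  a value uniformly on the integer grid (0.1 °C grid for temperature)
  within a band carrying that subscore. Every record therefore re-scores
  exactly to its drawn total — the round-trip property the tests hammer.
  Within-band correlation between vitals is deliberately not modelled.
- Death from a logistic model with log-odds ln 5.82 for MEWS >= 5 and
  ln 7.17 for medical admission (an optional HIV-positive effect,
  default off, can inject ln 4.23), with the intercept solved by
  bisection (tolerance 1e-10) so the marginal death probability over the
  discrete covariate distribution equals the target (default 5.5%).
  Survivors split discharged vs. on-ward at the published 41.4/53.1
  ratio.
- Nuisance covariates at the published margins: 45.1% medical service
  (54.1% of surgical patients preoperative), 53.3% male, 18.8% trauma,
  89.4% with an attendant, HIV unknown 25.2% and positive in 32.5% of
  known, admission source (53.8/30.0/16.2), age normal(42.8, 16.6)
  truncated at 18, pre-enrollment stay lognormal with median 9 days and
  log-SD 1.33 (matching the published IQR 4–24), ER-documentation flags
  independent Bernoulli with configurable rates.
- Self-discharge arm, **off by default**: when enabled (rate 62/530),
  flagged patients get outcome `self_discharged` with severity shifted in
  the direction the study reported — medical share 0.65, HIV-positive
  share 0.50 among known, and the MEWS mass tilted by 1.35^total. The arm
  defaults off because the published calibration marginals describe the
  analyzed cohort; enabling it is one parameter
  (`CohortParams.with_self_discharge()`). Magnitudes are configuration,
  not claims: the study published proportions, not a censoring
  mechanism.

Identical parameters and seed give byte-identical output; all draws come
from one `numpy` Generator in a fixed order.

`reference_cohort()` is a different object: a fully deterministic
synthetic reconstruction of the *published margins* — the two cutoff 2x2
tables (14/82/11/345 and 12/41/13/386), the service, sex, trauma and HIV
mortality splits that reproduce the published univariable odds ratios,
and the discharge disposition. Joints the study never published (exact
totals within the <4 and >=5 strata, covariate joints) are an arbitrary
deterministic fill, shuffled with a fixed seed within outcome blocks so
no covariate pattern is degenerate. It exists so that every derivable
published indicator can be recomputed exactly on desk-scale data.

What passing tests on generated cohorts do **not** show: anything about
correlations among vitals, about time trends, or about real-world
case-mix beyond the margins listed above.

## Simulation sizes and tolerances

Parameter recovery refits the generating two-predictor model on a 50,000
patient cohort and requires both odds ratios within 10% relative error;
at that size the Monte-Carlo SE of each log-OR is about 0.05, so the
band is ~4 SE wide. Coverage of the null-predictor CI uses 150 replicates
of n = 600 (binomial 3-SE acceptance band); deviance-GOF calibration uses
100 replicates of n = 2,000 against a KS test at the 1% level; the
misspecification power check uses one n = 20,000 cohort with a strong
omitted interaction. These sizes are the package's chosen operating
points for routine verification — large enough for the asymptotics the
checks rely on, small enough to run in seconds.

One numerical note: the cutoff-5 LR+ derived from the published counts is
0.48·427/41 = 4.9990 (the source table prints a truncated 4.99); reports
here show the count-derived value, 5.00 at two decimals. Similarly the
MEWS >= 4 prevalence is reported count-derived as 21.2% (96/452), and
"HIV positive" means 32.5% of known statuses, i.e. 24.3% of all patients.

## Known limitations

- The multivariable results of the source study (ORs 7.17/5.82, model
  AUROC 0.804, deviance 9.1282) cannot be reproduced without the original
  patient-level data; the package exercises them as parameter-recovery
  properties on synthetic cohorts instead. The degrees of freedom behind
  the published deviance statistic are unstated, which is why both the
  grouped and raw deviance are reported.
- The AVPU scale is used as recorded; Glasgow Coma Scale documentation is
  carried only as an ER-documentation flag, never converted.
- No negative predictive value, LR−, decision-curve analysis, survival
  modelling, penalized/Firth regression, or imputation: the analysis is a
  binary 7-day outcome pipeline by design.
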