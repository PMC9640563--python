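# Methods

## Scope and data model

`vftrend` analyses longitudinal series of Humphrey 10-2 visual-field
examinations.  The 68-location grid is generated from first principles: all
points with odd eccentricities |x|, |y| ≤ 9° subject to x² + y² ≤ 82 — the
unique circular cutoff over the odd-offset lattice yielding exactly 68
points — ordered row-major (y descending, x ascending).  Sensitivities are
stored as real numbers in [0, 40] dB (instrument range); measured values in
practice are integers, but predictions are not, so the type does not force
integrality.

Series preparation follows the cohort-inclusion logic of a retrospective
clinic study: unreliable tests (fixation losses > 20 % **or** false
positives > 15 %, strict inequalities, so boundary values are retained) are
dropped, the first 13 reliable tests are kept in time order, re-indexed
1…13, and time is rebased so the first retained test sits at 0 years.  Eyes
with fewer than 13 reliable tests are excluded and logged.  An alternative
reading — excluding any eye with an unreliable test — was rejected in
favour of filter-then-truncate, which matches how such series are assembled
in practice.

The mean deviation (MD) used here is the *unweighted* mean of total
deviations against a configurable normative grid (default: constant 33 dB
everywhere).  The instrument's MD is age-corrected and variance-weighted
from a proprietary normative database; only the ordering and slopes of MD
matter for this analysis, so the unweighted analogue suffices.
Eccentricity dependence of normal sensitivity within the central 10° is
small enough to ignore at the defaults.

## Trend models

Five models are fitted per location to (time, sensitivity):

| model | form | parameters | fitting |
|---|---|---|---|
| OLSLR | y = ax + b | a, b | closed-form least squares |
| Exponential | y = e^(ax+b) | a, b | least squares in dB space |
| Quadratic | y = ax² + bx + c | a, b, c | closed-form least squares |
| M-robust | y = ax + b | a, b | Huber IRLS |
| Logistic | y/40 = 1/(1+e^(ax+b)) | a, b | least squares on the 0–1 scale |

The fitting criterion for the exponential and logistic curves is not
canonical; least squares in the observation space (dB, or dB/40) was chosen
for comparability with the reference model and for determinism.  Both are
initialised from a straight-line fit of the log- (resp. negative-logit-)
transformed response and refined with Levenberg–Marquardt; the refined
solution is kept only if it does not increase the sum of squares, so the
reported objective never exceeds the initialiser's.  The logit initialiser
clamps y/40 to [0.01, 0.99] purely to keep the transform finite at 0 and
40 dB; the objective uses unclamped values.  Non-improving or failed
refinements fall back to the initialiser with `converged=False`.

M-estimation uses the de-facto standard Huber recipe: tuning constant
k = 1.345 (95 % Gaussian efficiency), scale σ̂ = median(|r|)/0.6745
re-estimated each iteration, weights min(1, kσ̂/|r|), starting from the OLS
solution, stopping when the largest coefficient change is below 1e-8 or
after 100 iterations.  If σ̂ < 1e-6 (at least half the residuals exactly
zero) the OLS fit is returned unchanged — on zero-residual data the two
estimators coincide exactly.  Each IRLS step is a strictly convex weighted
least-squares problem given non-degenerate times, so ties cannot occur and
the fit is deterministic.

Degenerate inputs: all-equal times raise a singular-design error; fewer
than 3 distinct times do so for the quadratic; an all-zero response is
degenerate for the exponential (b → −∞).  In the point-wise driver,
however, an all-zero (blind) location is given a floor-predicting
exponential fit (prediction ≡ 0, `converged=False`) rather than failing:
severe eyes routinely contain blind locations, and dropping whole windows
for them would exclude most of a severe cohort from the exponential arm.

Predictions are *not* truncated to [0, 40] dB by default (`clamp` is
available, and exposed as `--clamp-predictions` in the CLI): unclamped
errors preserve the differences between model classes, which is the object
of study.  Exponential and logistic predictions are bounded below by 0 (and
the logistic above by 40) by construction.

## Rolling evaluation and saturation

For horizon h ∈ {1, 2, 3} the fitting window grows from 5 tests (shorter
series are known to be unreliable for trend analysis) until the target is
the 13th examination: 8, 7, 6 windows respectively.  Per (eye, model,
horizon, window): fit point-wise on tests 1…n, predict each location at the
target test's actual time, and take the MAE over the 68 locations.  The MS
path fits the same model to the per-test mean sensitivity series directly
("predicted in the same way"), rather than averaging point-wise
predictions; for the logistic model MS is likewise divided by 40.

Cross-eye aggregation reports mean, SD (n−1), SE and the normal 95 % CI
(±1.96·SE).  The CI deliberately ignores fellow-eye correlation within
patients — it mirrors the single dashed reference line of the figures this
analysis produces; the mixed model handles the correlation in formal
comparisons.  The saturation rule: the best window is the argmin of mean
MAE (ties toward the longest window, matching "longest series, smallest
MAE"), and the number of VFs required is the smallest window whose mean MAE
is ≤ the best cell's upper CI bound (+1e-12 so exactly-zero-error tables
scan cleanly).  "Reaching" the CI is operationalised as crossing its upper
bound because mean MAE approaches its minimum from above.

Subgroups: severity splits on initial MD at −20 dB, progression on MD slope
at −0.25 dB/y; both source definitions use strict inequalities on both
sides, leaving the boundary undefined, so boundary eyes (within 1e-9 of the
threshold, to absorb floating-point noise in the OLS slope) are assigned to
the less-severe group.

## Model comparison

Per cell, the candidate's and reference's per-eye errors are stacked in
long format (two rows per eye) with a model indicator, and a linear mixed
model with a random intercept per *patient* is fitted (REML, statsmodels
`MixedLM`); "subject" is read as patient, since the stated purpose of the
random effect is to absorb the inclusion of both eyes of one patient.  The
indicator's coefficient is the estimated mean error difference, and its
Wald test gives the raw p.  The long-format layout (rather than difference
scores) lets the patient intercept absorb both within-patient and
within-eye pairing.  In the balanced one-eye-per-patient case this reduces
to a paired t-test, which is asserted in the tests (|Δp| ≤ 0.01 at 100
patients).  Cells with zero between-condition variance are resolved without
a model fit — identical errors give (0, 1); an exactly constant shift gives
(shift, 0) — because the Wald statistic is undefined at zero residual
variance.  Cells with fewer than 3 patients are refused.

Benjamini–Hochberg families are one (horizon, analysis path, subgroup)
table across all candidate models and windows — the organisation in which
such comparisons are reported.  Significance: adjusted p < 0.05.  NaN
p-values (unfittable cells) pass through unadjusted and do not count toward
the family size.

## Synthetic cohort generator

No real cohort of this kind is publicly deposited, so the generator
produces cohorts with the statistical structure the analysis assumes.
Defaults (all configurable, YAML-serialisable):

| parameter | default | meaning |
|---|---|---|
| n_patients / n_eyes | 133 / 180 | 47 bilateral patients |
| n_tests | 13 | scheduled reliable examinations per eye |
| interval_years_mean / jitter SD | 0.625 / 0.15 | ~6-month visits; 7.5 y over 12 intervals |
| baseline_md_mean / sd | −19.8 / 8.1 dB | severe-cohort initial damage |
| md_slope_mean / sd | −0.33 / 0.40 dB/y | slow global decay |
| within_patient_slope_correlation | 0.5 | fellow-eye similarity (unreported in source data; free parameter) |
| pointwise_slope_sd | 0.2 dB/y | spatial heterogeneity of decay |
| defect_correlation_length_deg | 4 | squared-exponential kernel length |
| defect_field_sd | 5 dB | amplitude of the baseline defect field |
| noise_sd_at_ceiling / floor | 1.5 / 4.0 dB | test-retest SD at 35 / 0 dB, linear in between |
| unreliable_test_rate | 0.05 | chance a visit spawns a failed test |
| round_to_integer | true | instrument reports whole dB |

Construction per eye: the baseline MD is drawn from a truncated normal on
[−33, 0] dB whose *location is recentred* so the realised mean equals the
configured mean (plain truncation of N(−19.8, 8.1) would shift the realised
mean to ≈ −19.1; the configured moments are taken to describe the realised
cohort).  The truncation necessarily shrinks the realised SD (to ≈ 7.0 dB);
only the mean is treated as a consistency target.  Fellow eyes share a
patient-level latent severity and slope factor (Gaussian copula for the
truncated MD marginal), giving the configured fellow-eye correlation.
Baseline sensitivities are the normative level plus a spatially correlated
Gaussian defect field, offset (by root-finding) so the clamped-[0, 35]
field hits the drawn MD exactly.  The 5 dB field amplitude is a compromise:
real severe 10-2 fields are more bimodal (deep focal defects next to
preserved regions), but a heavily floored baseline would make the
configured slope unrealisable (see below).

Point slopes are the eye slope plus a spatially correlated perturbation.
The truth trajectory is floored at 0 dB — progression stops at the floor —
and measurements are truth plus heteroscedastic Gaussian noise, censored to
[0, 40] and rounded.  Both mechanisms attenuate the *estimated* MD slope
relative to the raw point slopes (≈18 % at the defaults).  A clinical MD
slope is itself an estimate from floored, censored measurements, so the
configured slope is interpreted as the realised estimated trend: a common
offset is added to each eye's point slopes (root-finding again) such that
the OLS slope of the *expected measured* MD — the closed-form expectation
of clip(truth + noise, 0, 40) — over the scheduled visits equals the drawn
value.  Eyes too close to the floor cannot express steep decay at any
offset; they keep the closest feasible trend.  This is the generator's main
known limitation: the cohort-mean estimated slope sits within ~0.04 dB/y of
the configured value rather than matching it exactly, with the residue
attributable to near-blind eyes.

Unreliable tests are inserted *between* scheduled visits (a failed
examination is repeated at the next visit, as in clinical practice), and
the first test is always reliable, so the retained 13-test series keeps the
configured visit schedule and the mean first-to-thirteenth time stays at
~7.5 years.  Realised follow-up SD is ≈ 0.5 y — much tighter than a real
clinic's ≈ 2 y, because the generator follows a single per-protocol
schedule; inter-eye schedule heterogeneity is not modelled.

Also not modelled: SITA staircase psychophysics (noise is Gaussian, not
staircase-quantised), learning and fatigue effects, long-term drift of
reliability, media opacity, and any dependence between severity and
progression rate.  Passing tests on these cohorts therefore demonstrate the
pipeline's statistical behaviour under its stated assumptions, not clinical
performance on real series.

## Problem sizes and numerical settings

Study-scale checks use the default 180-eye cohort averaged over five seeds
(0–4) for the error-curve structure and generator-consistency tests; null
calibration of the testing chain uses 200 replicates of 8-cell families
with 40 single-eye patients; oracle equivalence uses 1000 random instances
per fitter.  Optimiser settings: Levenberg–Marquardt with max 2000
residual evaluations; IRLS tolerance 1e-8, 100 iterations; root-finding by
Brent's method at 1e-8…1e-10 tolerances.  All randomness flows through
`numpy.random.default_rng` seeds; every fitter is deterministic given its
input.
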