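# Methods

## The analysis in brief

The pipeline asks whether, for a given comorbidity, baseline BMI works as
a screening test for one-year disease incidence, and if so, at what
threshold. The estimand chain is: clean anthropometrics → one analyzable
row per patient (index visit, baseline BMI, covariates, per-comorbidity
status) → ROC of baseline BMI against incident status → AUROC gate →
Youden-optimal cut point. All steps are deterministic given the inputs
and a single top-level seed.

## Anthropometric cleaning

Cleaning is longitudinal and **per patient**: the plausibility statistics
(mean, SD, range) are computed within each patient's own series, which is
what makes a 180 lb → 810 lb transposition detectable against that
patient's other weights even though 810 lb is within a population-wide
plausible range for no one but still < 1000 lb.

Rules, applied in a **single pass** with statistics computed once on the
absolute-bound survivors:

* heights: remove > 90 in, < 44 in; if the per-patient sample SD exceeds
  2.5% of the mean, remove values deviating more than 1 SD from the mean;
* weights: remove > 1000 lb, < 55 lb; if the range ≥ 50 lb, remove values
  deviating more than 70% of the range from the mean; if the SD exceeds
  20% of the mean, remove values deviating more than 1 SD.

Conventions that had to be pinned down and are therefore explicit in code
and tests: sample SD (n − 1; a singleton series has SD 0, so conditional
rules never fire), strict inequalities (boundary values are kept), no
iteration to convergence (a second pass is a no-op only when the trigger
condition is stable — tested as such), and when a weight fails both
conditional rules the recorded reason is `range_rule`. Missing heights
are filled last-valid-forward then next-valid-backward, using only
heights that passed cleaning. Cleaning removes *measurements*, never
patients.

## Cohort and index visit

A candidate index visit has a computable BMI, some visit dated ≥ 365 days
earlier, and some visit ≥ 365 days later (which guarantees ≥ 3 visits
spanning ≥ 2 years and a full year of incidence follow-up). "One year" is
implemented as ≥ 365 days on both sides. Patients with several candidates
have one chosen uniformly at random from a stream keyed by a hash of
(seed, patient_id), so cohort membership is invariant to input row order
— a property the suite checks by shuffling. Exclusions (pregnancy or
cancer codes at any time; bariatric-registry membership) remove the
patient entirely; the age filter (18–75) applies at the index visit.

## Incidence and person-time

Status per comorbidity: *prevalent* if any matching code is dated at or
before index (closed boundary), *incident* if the first matching code
falls in the half-open window (index, index + 365 d], else *free*. Code
matching is prefix-based over normalized (uppercased, dot-stripped)
codes. Because the design guarantees one year of observed follow-up for
every at-risk patient, each contributes exactly one person-year and the
rate per 100 person-years is 100·incident/at-risk; no censoring model is
warranted by the fixed-window design.

## Median regression

The unadjusted contrast is exactly the difference of group sample medians
(numpy's midpoint convention at even n — a deterministic representative
of the minimizer interval). The adjusted contrast is the incidence
coefficient of a τ = 0.5 quantile regression with age (linear), sex,
race/ethnicity and smoking (reference-coded: female, White-NH,
nonsmoker). The fit solves the LP formulation of the check-loss problem
with HiGHS (sparse constraints), giving the exact minimizer rather than
an IRLS approximation; the test suite verifies loss agreement to 1e-6
against a brute-force enumeration of basic solutions and never-worse
losses than statsmodels' QuantReg. Confidence intervals are seeded
percentile bootstraps over patients (default 1000 resamples); the same
bootstrap machinery serves the cut-point comparisons, keeping inference
uniform across the package. On degenerate resamples (single class, or an
incidence indicator collinear with a covariate level) the replicate is
dropped; a degenerate observed design yields an undefined contrast, not
a crash.

## Cut points

Screening orientation is positive = BMI ≥ threshold. The threshold sweep
uses the observed unique BMI values plus ∓∞ sentinels, so the ROC always
contains (Se, Sp) = (1, 0) and (0, 1). AUROC is the trapezoidal area,
which equals Mann–Whitney concordance with ties counted ½ — asserted
exactly against an O(n²) oracle. The gate is strict (AUROC > 0.6); gated
or single-class subsets yield "not defined" results that stay in the
output tables rather than disappearing. The cut point is the observed BMI
maximizing J = Se + Sp − 1, ties broken toward the smaller BMI (the
earlier-screening direction). The prevalence variant uses prevalent-at-
index as the positive class against **all** non-prevalent patients
(future incident cases included) — a documented choice where either
denominator is defensible.

Bootstrap comparison of two cut points: patients resampled with
replacement within each group (unstratified by default; a stratified
switch exists), both cut points recomputed per resample, and the
two-sided p-value is 2·min(P(Δ ≤ 0), P(Δ ≥ 0)) with the add-one
correction (count + 1)/(m + 1). Resamples failing the AUROC gate are
redrawn up to 10 times, then counted missing with a warning.

## The synthetic-EHR generator

What it emulates: ~10.6 years of visits (per-patient Poisson count, mean
6), sex-specific heights, a truncated-normal baseline BMI (mean 29.1,
SD 7.0 kg/m², bounds 15–60), slow per-patient BMI drift (SD 0.3 kg/m²
per year) plus visit-level noise (SD 0.5), demographic mixtures matching
a large US academic-center cohort (55% female, 89% White non-Hispanic),
entry errors (5% missing heights; 1% height and 1% weight typos, split
between unit confusion — cm recorded as inches, kg as pounds — and
leading-digit transposition), baseline prevalence logistic in BMI and
age, and yearly incidence with a **step** of δ log-odds at a true
threshold θ, so a true cut point exists by construction (a smooth
logit-linear alternative is a config switch, giving a no-true-cut-point
regime). Default disease models land baseline prevalences near 7.5%
(diabetes), 21.5% (hypertension), 24.3% (hyperlipidemia) and 14%
(anxiety, with δ = 0 as a built-in null) at BMI 29 / age 45; realized
cohort prevalence is higher because onsets accumulating before a
patient's index visit also count as prevalent, as in a real EHR.

What it does not emulate — and what passing tests therefore do not show
about real data: correlated comorbidities, informative visit frequency
(sicker patients visiting more), BMI–age dependence, ICD coding delay or
miscoding (codes are emitted exactly at onset), within-patient
measurement drift artifacts, or realistic code ontologies (code sets are
toy prefixes, supplied via config).

Diagnosis events are emitted at the true onset date, which makes
truth-vs-pipeline classification checks exact; onsets are constrained to
the observation window (prevalent-at-start onsets are placed in its
first 30 days).

## Numerical and design choices

* Units: heights in inches, weights in pounds, BMI = 703·lb/in².
* Per-patient randomness is hash-keyed, never positional.
* Sensitivities/specificities are computed as single integer quotients
  (k/n), never as 1 − k′/n, so oracle comparisons can be exact.
* Problem sizes in the heavier tests — 20 replicates at n = 20,000 for
  threshold recovery, 200 replicates × 200 resamples at n = 2,000/group
  for bootstrap size, 50 replicates at n = 10,000/group for power — were
  chosen as the smallest scales at which the binomial/bootstrap noise
  bands quoted in the tests are meaningful.
* The bootstrap size/power study samples (BMI, label) pairs directly
  from the disease model (`simulate_screening_sample`) rather than
  regenerating full visit tables per replicate; threshold recovery, by
  contrast, runs the entire pipeline including corruption and cleaning.

## Known limitations

* The cut point is a plug-in estimate; no bias correction for the
  optimism of maximizing J in-sample is applied (the bootstrap
  comparisons inherit this).
* The person-time convention makes the per-100-person-year rate equal to
  the one-year cumulative incidence × 100; it is not an event-time rate.
* The adjusted median-regression CI is a percentile bootstrap; no
  asymptotic (sandwich) intervals are offered.
* `find_eligible_intervals` is per-patient and readable; the pipeline
  uses an equivalent vectorized path (`_candidate_index_table`) whose
  agreement is enforced by the row-order-invariance and window-property
  tests.
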