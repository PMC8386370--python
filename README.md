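# bmicut

Do BMI *cut points* exist for obesity-related comorbidities — thresholds
beyond which one-year disease incidence can be accurately detected — and
where do they lie? `bmicut` implements a complete, testable EHR-style
analysis pipeline for that question, aimed at epidemiologists and
biostatisticians working with longitudinal visit/diagnosis tables:

1. **Anthropometric cleaning** — per-patient longitudinal plausibility
   rules for heights and weights (absolute bounds, SD and range rules),
   carry-forward/backward height imputation, BMI = 703·lb/in².
2. **Cohort construction** — an *index visit* with a valid BMI, another
   visit ≥ 1 year before and another ≥ 1 year after; random interval
   selection for multi-eligible patients; pregnancy/cancer/bariatric
   registry exclusions; ages 18–75 at index.
3. **Incidence classification** — per comorbidity: *prevalent* (code at or
   before index), *incident* (first code within 365 days after index), or
   *free*; one-year incidence per 100 person-years.
4. **Median-BMI contrasts** — quantile (median) regression of baseline BMI
   on incidence status, unadjusted and adjusted for age, sex,
   race/ethnicity and smoking, with bootstrap CIs. The check-function loss
   Σᵢ ρ₀.₅(yᵢ − xᵢᵀβ) is minimized exactly by linear programming.
5. **Cut points** — BMI as a screening test (positive = BMI ≥ t):
   sensitivity/specificity swept over all observed BMI values; a cut point
   exists only when AUROC > 0.6, and is then the observed BMI maximizing
   the Youden index J = Se + Sp − 1. Subgroup cut points by sex and
   race/ethnicity, incidence-vs-prevalence contrasts, and cut-point
   comparisons via a 1000-resample patient-level bootstrap.

Because real institutional EHRs cannot be redistributed, the package
ships a **synthetic-EHR generator** (`bmicut.synthetic_ehr`) whose disease
models have a *known* threshold: yearly incidence is logistic with a step
of δ log-odds at a true BMI threshold θ. Every downstream stage is tested
against this ground truth (e.g. the pipeline recovers θ = 30 to within a
median absolute error ≤ 0.5 kg/m² at n = 20,000).

## Worked example

```sh
bmicut run --n-patients 5000 --seed 1 --bootstrap 200 --out demo
```

simulates 5,000 patients over a 10.6-year window (four toy comorbidities;
true thresholds θ: diabetes 31.0, hypertension 28.5, hyperlipidemia 27.0,
anxiety none — δ = 0), runs the whole pipeline (~4 min, most of it the
bootstrap), and writes 12 CSVs plus a manifest. `demo/cutpoints_overall.csv`:

```
comorbidity,auroc,youden,sensitivity_pct,specificity_pct,cutpoint,n_at_risk,n_incident
type_2_diabetes,0.738806,0.476382,74.7475,72.8907,31.34,2825,99
hypertension,0.633682,0.319884,67.7419,64.2465,28.5555,1763,124
hyperlipidemia,0.607008,0.242478,67.3469,56.9009,28.1393,1741,147
anxiety,0.551747,,,,,2803,71
```

Reading: diabetes passes the AUROC gate (0.739 > 0.6) and its estimated
cut point, 31.3 kg/m², sits next to the generator's true threshold 31.0;
at that threshold sensitivity is 74.7% and specificity 72.9%
(J = 0.476). Anxiety, generated with no BMI effect, fails the gate
(AUROC 0.552) and is reported as having no cut point. Companion tables
give incidence rates above/below each cut point
(`rates_above_below.csv`: diabetes 9.1 vs 1.2 per 100 person-years),
median-BMI contrasts (`median_contrasts.csv`: adjusted +6.5 kg/m² for
diabetes), cut points by sex and race/ethnicity with bootstrap p-values,
and incidence-vs-prevalence cut-point comparisons.

The same analyses are available as library functions
(`bmicut.find_cutpoint`, `bmicut.median_bmi_difference`,
`bmicut.bootstrap_compare_cutpoints`, …) on any cohort DataFrame with a
`baseline_bmi` column and per-comorbidity status columns.

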