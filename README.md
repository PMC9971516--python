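# score2val

External validation of the SCORE2 cardiovascular risk models in a
socioeconomically and ethnically diverse routine-care population —
as a reusable, fully testable pipeline.

## The problem

SCORE2 predicts the 10-year risk of fatal plus non-fatal
cardiovascular disease (CVD) from age, sex, current smoking, systolic
blood pressure and cholesterol, with four region-calibrated variants
(low/moderate/high/very-high risk regions of Europe). The models carry
no socioeconomic or ethnicity terms. Validating them in a Dutch
primary-care population stratified by disposable-household-income
quintile and country of origin asks: does the low-risk model (the one
intended for the Netherlands) stay calibrated in every subgroup, and
if not, would one of the higher-region models fit a subgroup better?

The registry data such a study runs on cannot be shared. This package
therefore implements the full analysis against a synthetic cohort
generator whose defaults encode the study population's composition —
covariate marginals, SES/ethnicity mixes, competing non-CVD mortality,
staggered entry and deregistration, missing-at-random masking — and
whose subgroup true risks are *designed* multiples of the SCORE2
low-model prediction, so every pipeline stage is testable against
known truth.

## What is inside

| module | role |
|---|---|
| `score2val.engine` | SCORE2 risk engine: `risk = 1 − exp(−exp(s1 + s2·ln(−ln(S0(10)^exp(lp)))))`, coefficients as configuration data; treatment thresholds (2.5/7.5% under age 50, 5/10% above) |
| `score2val.cohort` | entry determination, eligibility exclusions with flowchart, outcome/competing-event classification, baseline-nearest measurements, validated CSV round trip |
| `score2val.impute` | chained-equations imputation (Bayesian PMM) for blood pressure, cholesterol, SES; Rubin's-rules pooling |
| `score2val.metrics` | Aalen–Johansen cumulative incidence with variance, OE-ratio, decile calibration curves with LOESS, O(n log n) Harrell's C with analytic SE, minimum-events gate |
| `score2val.subgroups` | stratified orchestration (sex × SES × ethnicity), best-fitting-region selection, treatment-eligibility shift, sensitivity analyses |
| `score2val.simulate` | the synthetic cohort generator and scenario presets |
| `score2val.report` | forest plots, calibration plots, C-statistic tables, flowchart, run manifest |

The numbered scripts under `analysis/` drive the study end to end;
`docs/methods.md` documents the models, parameters and design choices.

## Worked example

```bash
python analysis/02_validate_overall.py --seed 0
```

generates a 40,000-person default-scenario cohort (sex-level true-risk
multipliers 1.30/1.22 over the low-model prediction), imputes m = 5
datasets, validates all four region models and prints:

```
analysis cohort: 39954 persons

Pooled OE-ratio (95% CI) and Harrell's C by sex and region model:
  female low       OE 1.26 (1.16-1.37)  C 0.678 (0.654-0.701)
  female moderate  OE 1.06 (0.97-1.15)  C 0.678 (0.654-0.701)
  female high      OE 0.80 (0.73-0.87)  C 0.678 (0.654-0.701)
  female very_high OE 0.40 (0.37-0.43)  C 0.678 (0.654-0.701)
  male   low       OE 1.29 (1.21-1.37)  C 0.669 (0.651-0.688)
  male   moderate  OE 1.01 (0.95-1.08)  C 0.669 (0.651-0.688)
  male   high      OE 0.95 (0.89-1.01)  C 0.669 (0.651-0.688)
  male   very_high OE 0.55 (0.52-0.59)  C 0.669 (0.651-0.688)

Best-fitting region model per sex:
  female|ses=all|eth=all: moderate
  male|ses=all|eth=all: moderate

Eligibility at the upper treatment threshold:
  female: 1.2% (low model) -> 4.2% (best-fitting)
  male: 7.6% (low model) -> 18.0% (best-fitting)
```

Reading it: the low-risk model underpredicts by the designed 30%/22%
(OE > 1, observed exceeding expected), the moderate model lands on
OE ≈ 1 for this degree of underprediction, the high/very-high models
overpredict (OE < 1) — and switching each sex to its best-fitting
model roughly doubles the share of people at or above the very-high-risk
treatment threshold. The C statistics are the same across regions
within a sex because recalibration is monotone. Forest plot,
calibration curves and tidy CSVs land in `results/overall/`.

`analysis/03_subgroup_validation.py` does the same for the
ethnicity-multiplier and SES-multiplier scenarios (designed subgroup
OEs of 1.92 for Surinamese men, 1.64 for women in the lowest income
quintile, and so on), and `analysis/04_sensitivity.py` runs the four
sensitivity analyses. All scripts accept `--full` for the study-scale
155,013-person cohort.

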