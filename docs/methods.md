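# Methods

`score2val` validates the four region-calibrated SCORE2 models — the
European 10-year risk equations for fatal plus non-fatal cardiovascular
disease (CVD) — in a routine-care cohort stratified by sex,
socioeconomic status (SES, disposable-household-income quintiles) and
ethnicity (Dutch, Surinamese, combined other). Because the registry
data such a validation runs on cannot be shared, the package pairs the
validation pipeline with a synthetic cohort generator that encodes the
study population's composition as designed, recoverable truth. This
note records the models, the parameter choices and their rationale, and
what the synthetic design can and cannot demonstrate.

## The risk engine

SCORE2 is a Fine–Gray (subdistribution-hazard) model. For a person with
predictors x the engine computes

    lp   = Σ_k β_k · z_k(x),       z_k centred/scaled transforms
    u    = 1 − S0(10)^exp(lp)      (uncalibrated 10-year risk)
    risk = 1 − exp(−exp(s1 + s2 · ln(−ln(1 − u))))

with sex-specific coefficients β, baseline survival S0(10), and one
(s1, s2) pair per risk region (low, moderate, high, very high). The
transforms are age (centred 60, scale 5 y), current smoking, systolic
blood pressure (120 mmHg, 20 mmHg), total and HDL cholesterol
(6 and 1.3 mmol/L, scales 1 and 0.5 mmol/L), plus the four
age-interaction products. All constants live in
`src/score2val/data/score2_coefficients.json` and are loaded, never
hard-coded; the term schema also accepts a single non-HDL-cholesterol
term (`variable: nonhdl`), since some cohorts record only that. The
engine reproduces the published worked example (50-year-old male
smoker, SBP 140, tchol 6.3, HDL 1.4: uncalibrated 5.4%, low-region
6.3%) to the printed precision.

One property worth knowing: the published recalibration scale pairs do
not order the four regions at every risk level. The cloglog curves for
the moderate and high regions cross near 2.9% uncalibrated risk in men
(0.5% in women), so a young non-smoker can have a *higher* predicted
risk under the moderate model than under the high model. Region
monotonicity holds above the crossing — i.e. throughout the clinically
relevant range — and the tests pin both facts.

Treatment categories use the ESC age-specific cut-offs: 2.5%/7.5%
under age 50, 5%/10% at 50–69, half-open intervals with the upper
category inclusive (risk equal to a threshold moves up). Age at
prediction (cohort entry) selects the pair.

## Cohort construction

Entry is the latest of GP-registration start, the study start
(2007-01-01) and the 40th birthday; a record is ineligible if entry
falls at/after the 70th birthday, the registration end or the study
end (2020-07-01). Exclusions — prior CVD, diabetes, statin or
diabetes-medication use before entry, registration span under
6 months — carry machine-readable reasons that partition the dropped
records (flowchart conservation is a tested invariant). The "at least
6 months" rule is applied to the total registration span; the source
text does not say whether it means span before entry, and the
alternative is a one-line change.

Follow-up runs from entry to the first of: CVD event or CVD death
(the combined endpoint), non-CVD death (the competing event), the 80th
birthday, the administrative end, or deregistration — with the reason
retained. A CVD event dated on the death date takes precedence, so the
combined endpoint is counted once. Person-years use a 365.25-day year.
Baseline measurements prefer GP over hospital sources; within a source
the latest value at/before entry wins, else the earliest within a
365-day post-entry window (configurable — the window bounds how far
into follow-up a "baseline" value may reach). Missing binary history
variables are assumed absent, and missing smoking status is resolved
to non-smoking, mirroring routine-care conventions.

## Validation metrics

**Observed risk** at the 10-year horizon is the Aalen–Johansen
cumulative incidence of CVD events with non-CVD death competing,
implemented vectorised (one pass over the sorted distinct event
times), with the counting-process (delta-method) variance; both agree
with lifelines' estimator to machine precision and the point estimates
with R `cmprsk::cuminc` (whose variance uses a different estimator —
the tests freeze its point estimates only). Using the cumulative
incidence rather than 1 − Kaplan–Meier matches the Fine–Gray
predictions being validated; with zero competing events the two
coincide exactly (tested).

**Calibration** is the OE-ratio — observed risk over mean predicted
probability — with the CI from the delta method on ln(OE), treating
the expected side as fixed: `exp(ln OE ± 1.96·√var(O)/O)`. Decile
calibration curves bin by predicted risk (stable sort, ties broken by
person id; fewer distinct predictions than bins merge with a warning)
with per-decile Aalen–Johansen observed risk and a LOESS smooth
(lowess over ~30 prediction slices, span 0.75, degree 1).

**Discrimination** is Harrell's C with competing deaths censored at
the death time and follow-up truncated at the horizon for consistency
with fixed-horizon predictions (both toggleable). The implementation
is two Fenwick-tree sweeps, O(n log n), with prediction ties counted
half; the variance is the pair-cluster U-statistic estimator
Σ_j (s_j − C·m_j)² / M² over per-subject pair sums, which the same
sweeps produce. Because recalibration is strictly monotone, C is
identical across the four region models within a sex stratum and is
computed once per stratum.

Subgroups need at least 200 observed events to be scored (reported
either way).

## Multiple imputation

Missingness is confined by design to SBP, total/HDL cholesterol and
the SES quintile. Each incomplete variable is imputed by predictive
mean matching under a Bayesian linear draw (σ² from the scaled inverse
chi-square, β from its normal posterior; 5 donors), cycling in order
of increasing missingness. Predictors follow the study's imputation
model: age, SBP, cholesterol, fasting glucose, eGFR, smoking, SES,
ethnicity dummies, follow-up time and event status — glucose and eGFR
are generated as auxiliary correlates precisely so the imputation
model can include them. Sex is added to that list as this package's
own choice: SBP and especially HDL are strongly sex-dimorphic (HDL
means differ by 0.3 mmol/L), and sex-pooled chained equations shrink
each sex's imputed values toward the other's, biasing mean predicted
risk by about ∓3% per sex — enough to distort every downstream
OE-ratio. The SES quintile is imputed by PMM on its
integer scale, so draws are always observed quintiles. Defaults:
m = 5 datasets, 10 sweeps; a 40-sweep diagnostic chain reports
per-variable means/SDs with a coarse trend flag. All draws come from
one seeded numpy Generator: runs are byte-identical under a fixed
seed.

Rubin's rules combine the per-imputation estimates: OE-ratios on the
log scale (delta-method variances), C on the identity scale with its
analytic variance; total variance W + (1 + 1/m)·B, normal-theory CIs
back-transformed where applicable.

## The synthetic cohort

The generator emulates the validation cohort's structure, not its
individuals. Defaults encode the study composition: 74,880 men and
80,133 women; ethnicity mixes (64/5.5/30.5% and 62/7/31%); SES
quintile mixes renormalised from the printed shares (which cover only
the ~94% with observed income); covariate marginals per sex — age
mean/SD 48.1/8.6 and 48.3/8.8 years, SBP 138/21 and 134/22 mmHg,
total cholesterol 5.5/1.1 mmol/L, HDL 1.2/0.3 and 1.5/0.4 mmol/L,
smoking 33.4%/32.1%.

Ages are drawn from a scaled Beta on [40, 70) matched to both printed
moments. A truncated normal cannot reach them (its SD maxes out near
7.3 at mean 48.1); the Beta solution concentrates extra mass near 40,
which is also what a dynamic cohort looks like when people age into
eligibility at their 40th birthday. Covariates are otherwise
independent within cells except a Gaussian-copula age–SBP correlation
(0.3 by default); fasting glucose and eGFR are noisy functions of age
and SBP.

**Designed truth.** Each person's true 10-year CVD probability is
`min(multiplier × low-model prediction, 0.95)`, the multiplier keyed
by (sex, ethnicity, SES) with wildcard fallback. Together with a
per-sex competing-death probability (0.032 men, 0.027 women — chosen
so the realised death proportions under partial exposure match the
study's 2.8%/2.4%) the pair is inverted exactly to constant
cause-specific hazards: Λ = −ln(1 − p1 − p2)/10 and
λ_j = p_j/(p1+p2)·Λ, so the cause-1 cumulative incidence at 10 years
equals the designed probability identically (quadrature-checked).
Latent exponential event times then race against censoring.

Scenario presets: `table1_default` (sex-level multipliers 1.30/1.22),
`ethnicity_multipliers` (men 1.21/1.92/1.40, women 1.15/1.86/1.20 for
Dutch/Surinamese/other), `ses_multipliers` (quintile extremes
1.54→1.17 men, 1.64→0.94 women, quintiles 2–4 log-linearly
interpolated), `null_calibration` (all 1).

**Entry and censoring.** A fraction (0.40) of persons is already
registered at the study start; the rest flow in uniformly until
mid-2019. Deregistration is exponential dropout at 0.004/year. These
two values were calibrated once, jointly, to the study's median
follow-up of 9.9 years (the generated median lands near 10.1; the
generated IQR is a little wider at the bottom and tops out at the
13.5-year study span, a known compromise of the two-parameter entry
model).

**Missingness.** Masking is missing-at-random: logistic in
standardised age and SES quintile (slopes 0.4 and 0.15 per quintile
toward lower SES), with the intercept solved per variable so the
marginal rates hit 31% (SBP), 35% (tchol), 36% (HDL), 6% (SES), 50%
(smoking). Smoking needs care: the study's 33.4%/32.1% prevalence
describes the *analysed* data, in which missing smoking counts as
non-smoking. The generator therefore draws latent smoking at
rate/(1 − 0.5), masks half, and computes the designed risk *after* the
assumed-non-smoker rule — so the designed multipliers are recoverable
by the pipeline exactly as specified. The truth table keeps the latent
status.

A truth table (designed risks, hazards, latent times, pre-masking
covariates) accompanies every cohort for oracle checks; the pipeline
never reads it.

**What passing does and does not show.** Recovery of the designed
multipliers demonstrates that the pipeline — imputation included — is
an unbiased measuring instrument under the study's composition,
missingness and censoring. It cannot validate the study's substantive
findings: the generator has no real between-person confounding
structure, no longitudinal measurement error, no household clustering,
and its true risks are by construction proportional to SCORE2
predictions within strata. Emergent checks (Harrell's C, the
expected-event total) test that the printed covariate marginals plus
the SCORE2 equations reproduce the study's discrimination and
prediction volume — they are not fitted.

## Numerical choices and degenerate inputs

- Recalibration rejects risks of exactly 0 or 1 (cloglog undefined)
  and non-positive scale2; the identity pair (0, 1) round-trips to
  1e-12 over a dense grid.
- The Aalen–Johansen variance terms guard the n_k = d_k boundary
  (contribution zero), and variances are floored at 0.
- PMM uses a 2×donors candidate window around the searchsorted
  insertion point; the Bayesian draw adds a tiny ridge (1e-8 scaled)
  to keep near-collinear designs factorisable.
- Best-region selection minimises |ln OE| with ties broken toward the
  lower-risk region (fixed region order).
- Same-day entry/terminal events get a nominal half-day of follow-up
  rather than zero.
- Eligibility shifts use the upper (very-high-risk) threshold by
  default; a flag switches to the lower cut-off, since "treatment
  threshold" is ambiguous between the two.

## Problem sizes

Unit and property tests run on cohorts of 8k–50k persons; the
study-scale checks (`tests/test_acceptance.py`, `scripts/acceptance.py`)
generate the full 155,013-person cohorts with m = 5 imputations and
10 sweeps, and the null-calibration coverage check uses 20 replicates
of 30k persons — sizes chosen so the designed truths are estimated
well inside the tolerances they are checked against.

## Known limitations

- Constant cause-specific hazards over follow-up: no ageing within
  follow-up, no secular trends.
- Competing mortality is sex-constant, not age-graded.
- The follow-up IQR is only approximately matched (see above).
- The OE CIs here are honest delta-method intervals; the narrow
  intervals a registry-scale study prints are not reproduced, and no
  attempt is made to match CI widths.
- Harrell's C pooling uses the identity scale; logit pooling would
  differ in the third decimal at these sample sizes.
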