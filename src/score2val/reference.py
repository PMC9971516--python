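"""Study reference constants for the validation cohort.

Baseline composition and performance figures of the Dutch routine-care
validation cohort (The Hague region, 2007–2020, ages 40–70) that the
synthetic generator emulates and the recovery checks compare against.
These are transcribed study-level summary statistics — data, not code.
"""

from __future__ import annotations

SEXES = ("male", "female")
ETHNICITIES = ("dutch", "surinamese", "other")

#: Cohort size by sex.
N_BY_SEX = {"male": 74_880, "female": 80_133}

#: Observed CVD events (combined endpoint: first stroke/MI or CVD death).
OBSERVED_EVENTS = {"male": 4251, "female": 2715}

#: Events predicted by the low-risk model over the whole cohort.
PREDICTED_EVENTS_LOW = 5495

#: Ethnicity composition by sex (dutch / surinamese / combined other).
ETHNICITY_MIX = {
    "male": {"dutch": 0.640, "surinamese": 0.055, "other": 0.305},
    "female": {"dutch": 0.621, "surinamese": 0.069, "other": 0.310},
}

#: SES quintile shares among persons with observed income, quintile 1 = lowest.
SES_MIX = {
    "male": (0.159, 0.127, 0.176, 0.233, 0.306),
    "female": (0.168, 0.139, 0.173, 0.206, 0.261),
}

#: Covariate marginals (mean, SD) by sex.
AGE_MEAN_SD = {"male": (48.1, 8.6), "female": (48.3, 8.8)}
SBP_MEAN_SD = {"male": (138.0, 21.0), "female": (134.0, 22.0)}
TCHOL_MEAN_SD = {"male": (5.5, 1.1), "female": (5.5, 1.1)}
HDL_MEAN_SD = {"male": (1.2, 0.3), "female": (1.5, 0.4)}

#: Current-smoking prevalence in the analysed data (missing assumed non-smoking).
SMOKING_RATE = {"male": 0.334, "female": 0.321}

#: Marginal missingness rates.
MISSING_RATES = {"sbp": 0.31, "tchol": 0.35, "hdl": 0.36, "smoking": 0.50, "ses": 0.06}

#: Follow-up distribution (years).
FOLLOWUP_MEDIAN = 9.9
FOLLOWUP_IQR = (5.7, 12.8)

#: Realised event-status proportions over follow-up, by sex.
EVENT_PROPORTIONS = {
    "male": {"cvd_event": 0.057, "competing_death": 0.028},
    "female": {"cvd_event": 0.034, "competing_death": 0.024},
}

#: Low-risk-model OE-ratios: overall, by ethnicity, and the SES-quintile
#: extremes (quintile 1 = lowest, quintile 5 = highest).
OE_LOW_OVERALL = {"male": 1.30, "female": 1.22}
OE_LOW_ETHNICITY = {
    "male": {"dutch": 1.21, "surinamese": 1.92, "other": 1.40},
    "female": {"dutch": 1.15, "surinamese": 1.86, "other": 1.20},
}
OE_LOW_SES_EXTREMES = {"male": (1.54, 1.17), "female": (1.64, 0.94)}

#: Harrell's C for the total population by sex (low-risk model).
C_STATISTIC_OVERALL = {"male": 0.70, "female": 0.72}

#: Fraction of CVD-event cases starting statin + antithrombotic medication.
MED_PROXY_SENSITIVITY = 0.93


def total_observed_events() -> int:
    """Total observed CVD events, summed over the sex-specific counts."""
    return sum(OBSERVED_EVENTS.values())


def ses_oe_interpolated(sex: str) -> dict[int, float]:
    """Per-quintile OE multipliers, log-linear between the printed extremes."""
    import math

    lo, hi = OE_LOW_SES_EXTREMES[sex]  # quintile 1, quintile 5
    step = (math.log(hi) - math.log(lo)) / 4.0
    return {q: math.exp(math.log(lo) + step * (q - 1)) for q in range(1, 6)}
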