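"""Synthetic routine-care cohort generator.

Generates person-level cohorts with the statistical structure the
validation pipeline assumes, calibrated to the study cohort's
composition: covariate marginals by sex, SES-quintile and ethnicity
mixes, subgroup-specific true-risk multipliers, competing non-CVD
mortality, staggered entry with administrative/deregistration
censoring, and missing-at-random masking of blood pressure,
cholesterol, smoking and income.

Designed truth: each person's true 10-year CVD probability is a
configured multiplier times their SCORE2 low-risk-model prediction
(capped), converted to a constant cause-specific hazard jointly with
the competing-death hazard by exact two-cause exponential inversion.
This encodes the observed-over-expected structure of the study as a
recoverable design parameter. A truth table is emitted alongside the
cohort for oracle checks only; the pipeline never reads it.

Smoking note: the cohort's smoking prevalence targets the analysed
prevalence (missing status is assumed non-smoking downstream), so the
generator draws latent smoking at ``rate / (1 - missing_rate)`` and
computes the designed risk after the masking + assumed-non-smoker rule
has been applied. True (latent) smoking is kept in the truth table.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from score2val import reference as ref
from score2val.engine import load_model_specs, predict_risk_table

__all__ = [
    "SyntheticCohortConfig",
    "scenario_config",
    "SCENARIOS",
    "generate",
    "invert_two_cause_hazards",
    "mask_missing",
]

SCENARIOS = (
    "table1_default",
    "ethnicity_multipliers",
    "ses_multipliers",
    "null_calibration",
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distribution parameters, subgroup multipliers and masking settings.

    Defaults reproduce the study cohort's composition and marginals; the
    ``multipliers`` map is keyed by ``(sex, ethnicity, ses_quintile)``
    with ``None`` as a wildcard, most specific key wins.
    """

    n_by_sex: dict = field(default_factory=lambda: dict(ref.N_BY_SEX))
    ethnicity_mix: dict = field(default_factory=lambda: {s: dict(m) for s, m in ref.ETHNICITY_MIX.items()})
    # printed quintile shares are among persons with observed income; renormalise
    ses_mix: dict = field(
        default_factory=lambda: {
            s: tuple(p / sum(m) for p in m) for s, m in ref.SES_MIX.items()
        }
    )
    age_mean_sd: dict = field(default_factory=lambda: dict(ref.AGE_MEAN_SD))
    sbp_mean_sd: dict = field(default_factory=lambda: dict(ref.SBP_MEAN_SD))
    tchol_mean_sd: dict = field(default_factory=lambda: dict(ref.TCHOL_MEAN_SD))
    hdl_mean_sd: dict = field(default_factory=lambda: dict(ref.HDL_MEAN_SD))
    smoking_rate: dict = field(default_factory=lambda: dict(ref.SMOKING_RATE))
    age_sbp_corr: float = 0.3
    multipliers: dict = field(default_factory=dict)  # (sex, eth|None, ses|None) -> mult
    competing_death_10y: dict = field(default_factory=lambda: {"male": 0.032, "female": 0.027})
    cvd_fatal_share: float = 0.2
    #: entry staggering: fraction already registered at study start; the
    #: remainder flows in uniformly until ``inflow_end``.
    entry_start_fraction: float = 0.40
    inflow_end: str = "2019-07-01"
    dereg_rate: float = 0.004  # per year
    missingness: dict = field(default_factory=lambda: dict(ref.MISSING_RATES))
    mar_age_slope: float = 0.4
    mar_ses_slope: float = 0.15
    med_proxy_sensitivity: float = ref.MED_PROXY_SENSITIVITY
    med_proxy_background: float = 0.08
    risk_cap: float = 0.95
    horizon: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sex, mix in self.ethnicity_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"ethnicity mix for {sex} must sum to 1")
        for sex, mix in self.ses_mix.items():
            if abs(sum(mix) - 1.0) > 1e-6:
                raise ValueError(f"ses mix for {sex} must sum to 1")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be positive")
        for rate in self.missingness.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")

    def multiplier(self, sex: str, ethnicity: str, ses: int) -> float:
        for key in (
            (sex, ethnicity, ses),
            (sex, None, ses),
            (sex, ethnicity, None),
            (sex, None, None),
        ):
            if key in self.multipliers:
                return self.multipliers[key]
        return 1.0


def scenario_config(
    name: str, seed: int = 0, n_by_sex: dict | None = None, **overrides
) -> SyntheticCohortConfig:
    """Build one of the shipped scenario presets.

    ``table1_default`` applies the overall sex-level OE multipliers;
    ``ethnicity_multipliers`` and ``ses_multipliers`` apply the
    sex-by-ethnicity and sex-by-SES-quintile multipliers (quintiles 2–4
    log-linearly interpolated between the reported extremes);
    ``null_calibration`` sets every multiplier to 1.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    mult: dict = {}
    if name == "table1_default":
        for sex, m in ref.OE_LOW_OVERALL.items():
            mult[(sex, None, None)] = m
    elif name == "ethnicity_multipliers":
        for sex, by_eth in ref.OE_LOW_ETHNICITY.items():
            for eth, m in by_eth.items():
                mult[(sex, eth, None)] = m
    elif name == "ses_multipliers":
        for sex in ref.SEXES:
            for q, m in ref.ses_oe_interpolated(sex).items():
                mult[(sex, None, q)] = m
    kwargs = dict(multipliers=mult, seed=seed)
    if n_by_sex is not None:
        kwargs["n_by_sex"] = n_by_sex
    kwargs.update(overrides)
    return SyntheticCohortConfig(**kwargs)


def invert_two_cause_hazards(
    target_cif: float, competing_cif: float, horizon: float = 10.0
) -> tuple[float, float]:
    """Constant cause-specific hazards hitting both cumulative incidences.

    With constant hazards (l1, l2) and independent censoring, the
    cause-j cumulative incidence at t is ``l_j/(l1+l2) (1 - e^{-(l1+l2)t})``;
    given targets (p1, p2) the inversion is exact:
    ``L = -ln(1-p1-p2)/T`` and ``l_j = p_j/(p1+p2) L``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if target_cif < 0 or competing_cif < 0 or target_cif + competing_cif >= 1:
        raise ValueError(
            f"infeasible CIF pair ({target_cif}, {competing_cif}): must be >= 0 and sum < 1"
        )
    total = target_cif + competing_cif
    if total == 0:
        return 0.0, 0.0
    lam = -math.log1p(-total) / horizon
    return target_cif / total * lam, competing_cif / total * lam


def _hazards_vec(p1: np.ndarray, p2: np.ndarray, horizon: float):
    total = p1 + p2
    if (total >= 1).any():
        raise ValueError("designed CIFs sum to >= 1 for some persons")
    lam = np.where(total > 0, -np.log1p(-total) / horizon, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, p1 / np.where(total > 0, total, 1.0), 0.0)
    return share * lam, (1.0 - share) * lam


def _draw_age(z: np.ndarray, mean: float, sd: float, lo: float, hi: float):
    """Map standard-normal draws to a bounded age distribution.

    A Beta distribution rescaled to [lo, hi) matched to the target mean
    and SD. (A truncated normal on [40, 70) cannot reach the cohort's
    printed moments — its SD maxes out well below 8.6 at mean 48.1; the
    Beta shape additionally concentrates mass near 40, mirroring people
    ageing into eligibility at their 40th birthday in a dynamic cohort.)
    """
    from scipy.stats import beta as beta_dist

    span = hi - lo
    m = (mean - lo) / span
    v = (sd / span) ** 2
    if not 0 < m < 1 or v >= m * (1 - m):
        raise ValueError(f"infeasible bounded moments mean={mean}, sd={sd} on [{lo}, {hi})")
    a = m * (m * (1 - m) / v - 1.0)
    b = a * (1 - m) / m
    u = ndtr(z)
    return lo + span * beta_dist.ppf(u, a, b)


def _calibrated_mask(
    rng: np.random.Generator,
    rate: float,
    z_age: np.ndarray,
    ses: np.ndarray,
    age_slope: float,
    ses_slope: float,
) -> np.ndarray:
    """MAR mask: logistic in age and SES, intercept solved to hit the rate."""
    if rate <= 0:
        return np.zeros(len(z_age), dtype=bool)
    if rate >= 1:
        return np.ones(len(z_age), dtype=bool)
    lin = age_slope * z_age + ses_slope * (3.0 - ses)

    def mean_rate(c):
        return expit(c + lin).mean() - rate

    c0 = brentq(mean_rate, -20.0, 20.0, xtol=1e-10)
    return rng.random(len(z_age)) < expit(c0 + lin)


def mask_missing(
    cohort: pd.DataFrame, config: SyntheticCohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Apply MAR masking to a complete cohort table.

    Blood pressure, cholesterol and SES values (with their measurement
    metadata) are set missing at the configured marginal rates with
    logistic dependence on age and SES quintile; masked smoking is
    tagged ``assumed_nonsmoker`` and its value cleared (the pipeline
    resolves it to non-smoking).
    """
    out = cohort.copy()
    age = out["age_entry"] if "age_entry" in out else out["_age"]
    z_age = (age.to_numpy(dtype=float) - age.mean()) / age.std()
    ses = out["ses_quintile"].to_numpy(dtype=float)
    for var in ("sbp", "tchol", "hdl"):
        rate = config.missingness.get(var, 0.0)
        mask = _calibrated_mask(rng, rate, z_age, ses, config.mar_age_slope, config.mar_ses_slope)
        out.loc[mask, var] = np.nan
        for extra in (f"{var}_date", f"{var}_source"):
            if extra in out:
                out.loc[mask, extra] = pd.NaT if extra.endswith("date") else pd.NA
    rate = config.missingness.get("smoking", 0.0)
    mask = _calibrated_mask(rng, rate, z_age, ses, config.mar_age_slope, config.mar_ses_slope)
    out["smoking"] = out["smoking"].astype("boolean")
    out.loc[mask, "smoking"] = pd.NA
    if "smoking_source" in out:
        out.loc[mask, "smoking_source"] = "assumed_nonsmoker"
    rate = config.missingness.get("ses", 0.0)
    mask = _calibrated_mask(rng, rate, z_age, ses, config.mar_age_slope, config.mar_ses_slope)
    out.loc[mask, "ses_quintile"] = np.nan
    return out


def generate(
    config: SyntheticCohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, truth) tables under the configured scenario.

    Deterministic for a fixed ``config.seed``: a single numpy Generator
    drives all draws in a fixed order (composition, covariates, entry,
    masking, event times, flags).
    """
    rng = np.random.default_rng(config.seed)
    specs = load_model_specs()
    study_start = pd.Timestamp("2007-01-01")
    admin_end = pd.Timestamp("2020-07-01")
    inflow_end = pd.Timestamp(config.inflow_end)

    frames = []
    for sex in ("male", "female"):
        n = int(config.n_by_sex[sex])
        eth_labels = list(config.ethnicity_mix[sex])
        eth = rng.choice(eth_labels, size=n, p=list(config.ethnicity_mix[sex].values()))
        ses = rng.choice(np.arange(1, 6), size=n, p=list(config.ses_mix[sex]))

        z_age = rng.standard_normal(n)
        z_sbp = config.age_sbp_corr * z_age + math.sqrt(
            1 - config.age_sbp_corr**2
        ) * rng.standard_normal(n)
        age = _draw_age(z_age, *config.age_mean_sd[sex], 40.0, 70.0)
        sbp_m, sbp_s = config.sbp_mean_sd[sex]
        sbp = np.clip(sbp_m + sbp_s * z_sbp, 75.0, 260.0)
        tchol = np.clip(
            rng.normal(*config.tchol_mean_sd[sex], size=n), 2.5, 12.0
        )
        hdl = np.clip(rng.normal(*config.hdl_mean_sd[sex], size=n), 0.4, None)
        hdl = np.minimum(hdl, tchol - 0.5)
        glucose = np.round(
            4.2 + 0.02 * (age - 48.0) + 0.01 * (sbp - 135.0) + 0.5 * rng.standard_normal(n), 2
        )
        egfr = np.round(np.clip(104.0 - 0.75 * (age - 40.0) + 12.0 * rng.standard_normal(n), 25.0, 150.0), 1)

        miss_smk = config.missingness.get("smoking", 0.0)
        latent_rate = min(config.smoking_rate[sex] / max(1.0 - miss_smk, 1e-9), 0.95)
        smoking_latent = rng.random(n) < latent_rate

        # entry staggering: a block registered before the study start,
        # the rest flowing in uniformly
        at_start = rng.random(n) < config.entry_start_fraction
        inflow_span = (inflow_end - study_start).days
        entry_offset = np.where(
            at_start, 0.0, rng.random(n) * inflow_span
        )
        entry = study_start + pd.to_timedelta(np.floor(entry_offset), unit="D")
        pre_reg_days = rng.integers(182, 3650, size=n)
        reg_start = entry.where(
            ~at_start, study_start - pd.to_timedelta(pre_reg_days, unit="D")
        )
        dereg_years = rng.exponential(1.0 / max(config.dereg_rate, 1e-12), size=n)
        reg_end = entry + pd.to_timedelta(
            np.minimum(np.ceil(dereg_years * 365.25), 40.0 * 365.25), unit="D"
        )

        meas_offset = rng.integers(0, 300, size=n)
        meas_date = entry - pd.to_timedelta(meas_offset, unit="D")
        source = np.where(rng.random(n) < 0.85, "GP", "hospital")

        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "ethnicity": eth,
                    "ses_quintile": ses.astype(float),
                    "_age": age,
                    "sbp": np.round(sbp, 1),
                    "tchol": np.round(tchol, 2),
                    "hdl": np.round(hdl, 2),
                    "glucose": glucose,
                    "egfr": egfr,
                    "smoking": smoking_latent,
                    "smoking_source": "coded",
                    "entry_date": entry,
                    "registration_start": reg_start,
                    "registration_end": reg_end,
                    "meas_date": meas_date,
                    "meas_source": source,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    n_total = len(df)
    df["person_id"] = [f"P{i:07d}" for i in range(n_total)]
    df["birth_date"] = df["entry_date"] - pd.to_timedelta(
        np.round(df["_age"].to_numpy() * 365.25).astype(int), unit="D"
    )

    truth_smoking = df["smoking"].copy()
    truth_values = df[
        ["person_id", "sex", "ethnicity", "ses_quintile", "_age", "sbp", "tchol", "hdl"]
    ].copy()

    # masking before the designed risk: the truth multiplier applies to
    # the prediction as the pipeline will compute it (assumed non-smoker)
    masked = mask_missing(df, config, rng)
    analysis = masked.copy()
    analysis["smoking"] = analysis["smoking"].fillna(False).astype(bool)
    pred_frame = pd.DataFrame(
        {
            "age": df["_age"],
            "sex": df["sex"],
            "smoking": analysis["smoking"],
            "sbp": df["sbp"],
            "tchol": df["tchol"],
            "hdl": df["hdl"],
        }
    )
    pred_low = predict_risk_table(pred_frame, specs, region="low")

    mult = np.array(
        [
            config.multiplier(s, e, int(q))
            for s, e, q in zip(df["sex"], df["ethnicity"], df["ses_quintile"])
        ]
    )
    p1_raw = mult * pred_low
    n_capped = int((p1_raw > config.risk_cap).sum())
    if n_capped:
        warnings.warn(f"{n_capped} designed risks capped at {config.risk_cap}", stacklevel=2)
    p1 = np.minimum(p1_raw, config.risk_cap)
    p2 = df["sex"].map(config.competing_death_10y).to_numpy(dtype=float)
    lam1, lam2 = _hazards_vec(p1, p2, config.horizon)

    u1, u2 = rng.random(n_total), rng.random(n_total)
    with np.errstate(divide="ignore"):
        t1 = np.where(lam1 > 0, -np.log(u1) / np.where(lam1 > 0, lam1, 1.0), np.inf)
        t2 = np.where(lam2 > 0, -np.log(u2) / np.where(lam2 > 0, lam2, 1.0), np.inf)
    t_event = np.minimum(t1, t2)
    cause = np.where(t1 <= t2, 1, 2)

    admin_years = (admin_end - df["entry_date"]).dt.days / 365.25
    age80_years = 80.0 - df["_age"].to_numpy()
    dereg_years_eff = (df["registration_end"] - df["entry_date"]).dt.days / 365.25
    censor_years = np.minimum.reduce(
        [admin_years.to_numpy(), age80_years, dereg_years_eff.to_numpy()]
    )
    observed_event = t_event < censor_years

    fatal = rng.random(n_total) < config.cvd_fatal_share
    # unobserved latent times can be centuries out; only observed ones get dates
    event_days = pd.to_timedelta(
        np.ceil(np.where(observed_event, t_event, 0.0) * 365.25), unit="D"
    )
    cvd_event_date = pd.Series(pd.NaT, index=df.index)
    death_date = pd.Series(pd.NaT, index=df.index)
    death_cause = pd.Series(pd.NA, index=df.index, dtype=object)
    is_cvd = observed_event & (cause == 1)
    is_comp = observed_event & (cause == 2)
    cvd_event_date[is_cvd & ~fatal] = (df["entry_date"] + event_days)[is_cvd & ~fatal]
    death_date[is_cvd & fatal] = (df["entry_date"] + event_days)[is_cvd & fatal]
    death_cause[is_cvd & fatal] = "cvd"
    death_date[is_comp] = (df["entry_date"] + event_days)[is_comp]
    death_cause[is_comp] = "non_cvd"

    nonfatal_cvd = is_cvd & ~fatal
    proxy = rng.random(n_total) < np.where(
        nonfatal_cvd, config.med_proxy_sensitivity, config.med_proxy_background
    )

    subarea = rng.random(n_total) < expit(-0.8 + 0.25 * (3.0 - df["ses_quintile"].to_numpy()))

    cohort = pd.DataFrame(
        {
            "person_id": df["person_id"],
            "sex": df["sex"],
            "birth_date": df["birth_date"],
            "registration_start": df["registration_start"],
            "registration_end": df["registration_end"],
            "ethnicity": masked["ethnicity"],
            "ses_quintile": masked["ses_quintile"],
            "smoking": masked["smoking"],
            "smoking_source": masked["smoking_source"],
            "sbp": masked["sbp"],
            "sbp_date": df["meas_date"].where(masked["sbp"].notna(), pd.NaT),
            "sbp_source": pd.Series(df["meas_source"]).where(masked["sbp"].notna(), pd.NA),
            "tchol": masked["tchol"],
            "tchol_date": df["meas_date"].where(masked["tchol"].notna(), pd.NaT),
            "tchol_source": pd.Series(df["meas_source"]).where(masked["tchol"].notna(), pd.NA),
            "hdl": masked["hdl"],
            "hdl_date": df["meas_date"].where(masked["hdl"].notna(), pd.NaT),
            "hdl_source": pd.Series(df["meas_source"]).where(masked["hdl"].notna(), pd.NA),
            "glucose": df["glucose"],
            "egfr": df["egfr"],
            "prior_cvd": False,
            "diabetes": False,
            "statin_use": False,
            "diabetes_medication": False,
            "cvd_event_date": cvd_event_date,
            "death_date": death_date,
            "death_cause": death_cause,
            "med_proxy_start": proxy,
            "subarea": subarea,
        }
    )

    truth = pd.DataFrame(
        {
            "person_id": truth_values["person_id"],
            "sex": truth_values["sex"],
            "ethnicity": truth_values["ethnicity"],
            "ses_quintile": truth_values["ses_quintile"],
            "age_entry": truth_values["_age"],
            "sbp": truth_values["sbp"],
            "tchol": truth_values["tchol"],
            "hdl": truth_values["hdl"],
            "smoking_latent": truth_smoking,
            "smoking_analysis": analysis["smoking"],
            "pred_low_design": pred_low,
            "multiplier": mult,
            "true_risk_10y": p1,
            "competing_risk_10y": p2,
            "lambda_event": lam1,
            "lambda_competing": lam2,
            "latent_event_time": t_event,
            "latent_cause": cause,
            "censor_time": censor_years,
        }
    )
    return cohort, truth
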