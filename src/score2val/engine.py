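"""SCORE2 risk engine.

Computes 10-year cardiovascular disease (CVD) risk from the SCORE2
Fine–Gray model: a linear predictor over centred/scaled risk factors
(age, current smoking, systolic blood pressure, total and HDL
cholesterol, plus age-interaction terms), the uncalibrated risk
``1 - S0(10)**exp(lp)``, and the region recalibration
``1 - exp(-exp(scale1 + scale2 * cloglog(risk)))`` with
``cloglog(r) = ln(-ln(1 - r))`` for the four European risk regions
(low, moderate, high, very_high).

All numeric model constants are configuration data loaded from a JSON
file (see :func:`load_model_specs`); the engine never hard-codes them.
The term schema supports either total+HDL cholesterol (the published
parameterisation) or a single non-HDL cholesterol term, since cohort
sources differ in which they record.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "REGIONS",
    "RiskFactorProfile",
    "TermSpec",
    "Score2ModelSpec",
    "RiskPrediction",
    "TreatmentCategory",
    "load_model_specs",
    "transform_profile",
    "linear_predictor",
    "uncalibrated_risk",
    "recalibrate",
    "predict_risk",
    "predict_risk_table",
    "treatment_category",
]

#: Region labels in increasing background-risk order.
REGIONS = ("low", "moderate", "high", "very_high")

_VALID_VARIABLES = {"age", "smoking", "sbp", "tchol", "hdl", "nonhdl"}


@dataclass(frozen=True)
class RiskFactorProfile:
    """One person's predictor values at cohort entry.

    age in years (40 <= age < 70 at entry), sbp in mmHg, cholesterol in
    mmol/L. ``smoking`` is current smoking.
    """

    age: float
    sex: str
    smoking: bool
    sbp: float
    tchol: float
    hdl: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (40.0 <= self.age < 70.0):
            raise ValueError(f"age must be in [40, 70), got {self.age}")
        for name in ("sbp", "tchol", "hdl"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        if self.hdl >= self.tchol:
            raise ValueError(
                f"hdl ({self.hdl}) must be below total cholesterol ({self.tchol})"
            )

    def value(self, variable: str) -> float:
        if variable == "nonhdl":
            return self.tchol - self.hdl
        if variable == "smoking":
            return float(self.smoking)
        return float(getattr(self, variable))


@dataclass(frozen=True)
class TermSpec:
    """One model term: beta * (x - center)/scale, optionally times centred age."""

    name: str
    variable: str
    center: float
    scale: float
    beta: float
    interacts_with_age: bool = False

    def __post_init__(self) -> None:
        if self.variable not in _VALID_VARIABLES:
            raise ValueError(f"unknown term variable {self.variable!r}")
        if self.scale == 0:
            raise ValueError("term scale must be nonzero")


@dataclass(frozen=True)
class Score2ModelSpec:
    """Sex-specific SCORE2 coefficients, baseline survival and region scales."""

    sex: str
    terms: tuple[TermSpec, ...]
    baseline_survival_10y: float
    scales: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0.0 < self.baseline_survival_10y < 1.0):
            raise ValueError("baseline_survival_10y must lie in (0, 1)")
        if set(self.scales) != set(REGIONS):
            raise ValueError(
                f"scales must cover exactly the regions {REGIONS}, got {set(self.scales)}"
            )
        for region, (_, s2) in self.scales.items():
            if s2 <= 0:
                raise ValueError(f"scale2 must be > 0 for region {region!r}")
        age_terms = [t for t in self.terms if t.variable == "age" and not t.interacts_with_age]
        if len(age_terms) != 1:
            raise ValueError("spec must contain exactly one main age term")

    @property
    def age_term(self) -> TermSpec:
        return next(t for t in self.terms if t.variable == "age" and not t.interacts_with_age)


@dataclass(frozen=True)
class RiskPrediction:
    linear_predictor: float
    uncalibrated_risk: float
    risk_by_region: Mapping[str, float]


@dataclass(frozen=True)
class TreatmentCategory:
    category: str  # low_to_moderate | high | very_high
    thresholds_used: tuple[float, float]  # percent


def load_model_specs(path=None) -> dict[str, Score2ModelSpec]:
    """Load the sex-specific model specs from a coefficient JSON file.

    With no ``path`` the packaged SCORE2 configuration is used. The JSON
    schema is ``{model: {sex: {terms: [...], s0_10, scales}}}``.
    """
    if path is None:
        text = (
            resources.files("score2val.data")
            .joinpath("score2_coefficients.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    model_keys = [k for k in raw if isinstance(raw[k], dict)]
    if len(model_keys) != 1:
        raise ValueError(f"expected exactly one model entry, got {model_keys}")
    model = raw[model_keys[0]]
    specs: dict[str, Score2ModelSpec] = {}
    for sex in ("male", "female"):
        if sex not in model:
            raise ValueError(f"model config missing sex {sex!r}")
        block = model[sex]
        terms = tuple(
            TermSpec(
                name=t["name"],
                variable=t.get("variable", t["name"]),
                center=float(t["center"]),
                scale=float(t["scale"]),
                beta=float(t["beta"]),
                interacts_with_age=bool(t.get("interacts_with_age", False)),
            )
            for t in block["terms"]
        )
        scales = {r: (float(s[0]), float(s[1])) for r, s in block["scales"].items()}
        specs[sex] = Score2ModelSpec(
            sex=sex,
            terms=terms,
            baseline_survival_10y=float(block["s0_10"]),
            scales=scales,
        )
    return specs


def transform_profile(profile: RiskFactorProfile, spec: Score2ModelSpec) -> np.ndarray:
    """Evaluate each model term for one profile (without the coefficients).

    Returns one value per ``spec.terms`` entry: ``(x - center)/scale``,
    multiplied by the centred/scaled age for age-interaction terms.
    """
    if profile.sex != spec.sex:
        raise ValueError(f"profile sex {profile.sex!r} does not match spec sex {spec.sex!r}")
    at = spec.age_term
    cage = (profile.value("age") - at.center) / at.scale
    values = np.empty(len(spec.terms))
    for i, t in enumerate(spec.terms):
        v = (profile.value(t.variable) - t.center) / t.scale
        if t.interacts_with_age:
            v *= cage
        values[i] = v
    return values


def linear_predictor(terms: Iterable[float], spec: Score2ModelSpec) -> float:
    """Inner product of term values with the spec's coefficients."""
    values = np.asarray(list(terms), dtype=float)
    betas = np.array([t.beta for t in spec.terms])
    if values.shape != betas.shape:
        raise ValueError(
            f"term vector length {values.shape} does not match spec ({betas.shape})"
        )
    return float(values @ betas)


def uncalibrated_risk(lp: float, spec: Score2ModelSpec) -> float:
    """10-year risk before region recalibration: ``1 - S0(10)**exp(lp)``."""
    if not math.isfinite(lp):
        raise ValueError(f"linear predictor must be finite, got {lp}")
    return 1.0 - spec.baseline_survival_10y ** math.exp(lp)


def recalibrate(risk, scale1: float, scale2: float):
    """Region recalibration on the complementary-log-log scale.

    ``1 - exp(-exp(scale1 + scale2 * ln(-ln(1 - risk))))``; the identity
    for ``(scale1, scale2) = (0, 1)`` and strictly increasing in ``risk``
    whenever ``scale2 > 0``. Accepts scalars or arrays.
    """
    if scale2 <= 0:
        raise ValueError(f"scale2 must be > 0, got {scale2}")
    r = np.asarray(risk, dtype=float)
    if np.any((r <= 0.0) | (r >= 1.0)):
        raise ValueError("risk must lie strictly inside (0, 1) for recalibration")
    out = -np.expm1(-np.exp(scale1 + scale2 * np.log(-np.log1p(-r))))
    return float(out) if np.isscalar(risk) or out.ndim == 0 else out


def predict_risk(
    profile: RiskFactorProfile, spec: Score2ModelSpec, region: str = "all"
) -> RiskPrediction:
    """Full prediction: transforms -> linear predictor -> recalibrated risk.

    ``region`` may be one of the four region labels or ``"all"``.
    """
    if region != "all" and region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS} or 'all'")
    lp = linear_predictor(transform_profile(profile, spec), spec)
    raw = uncalibrated_risk(lp, spec)
    wanted = REGIONS if region == "all" else (region,)
    by_region = {r: recalibrate(raw, *spec.scales[r]) for r in wanted}
    return RiskPrediction(linear_predictor=lp, uncalibrated_risk=raw, risk_by_region=by_region)


def predict_risk_table(
    df, specs: Mapping[str, Score2ModelSpec], region: str
) -> np.ndarray:
    """Vectorised region-recalibrated 10-year risk for a cohort table.

    ``df`` needs columns ``age, sex, smoking, sbp, tchol, hdl`` (sex coded
    'male'/'female'; smoking boolean, missing smoking treated as
    non-smoking per the assumed-absent convention). Missing values in any
    continuous predictor raise: imputation must happen upstream.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    n = len(df)
    risk = np.full(n, np.nan)
    sex_arr = df["sex"].to_numpy()
    smoking = df["smoking"].astype("boolean").fillna(False).to_numpy(dtype=bool).astype(float)
    cols = {c: df[c].to_numpy(dtype=float) for c in ("age", "sbp", "tchol", "hdl")}
    for c in ("age", "sbp", "tchol", "hdl"):
        if np.isnan(cols[c]).any():
            raise ValueError(
                f"missing {c} values: impute before prediction ({int(np.isnan(cols[c]).sum())} missing)"
            )
    values = dict(cols)
    values["smoking"] = smoking
    values["nonhdl"] = cols["tchol"] - cols["hdl"]
    for sex, spec in specs.items():
        mask = sex_arr == sex
        if not mask.any():
            continue
        at = spec.age_term
        cage = (values["age"][mask] - at.center) / at.scale
        lp = np.zeros(mask.sum())
        for t in spec.terms:
            v = (values[t.variable][mask] - t.center) / t.scale
            if t.interacts_with_age:
                v = v * cage
            lp += t.beta * v
        raw = 1.0 - spec.baseline_survival_10y ** np.exp(lp)
        s1, s2 = spec.scales[region]
        risk[mask] = recalibrate(raw, s1, s2)
    if np.isnan(risk).any():
        bad = set(sex_arr[np.isnan(risk)])
        raise ValueError(f"rows with unrecognised sex labels: {bad}")
    return risk


def treatment_category(risk: float, age: float) -> TreatmentCategory:
    """Classify a predicted risk against the age-specific ESC thresholds.

    Under age 50 the cut-offs are 2.5%/7.5%; from age 50 they are 5%/10%.
    Intervals are half-open with the upper category inclusive
    (risk == upper bound => very_high).
    """
    if not (0.0 <= risk <= 1.0):
        raise ValueError(f"risk must lie in [0, 1], got {risk}")
    lower, upper = (2.5, 7.5) if age < 50 else (5.0, 10.0)
    pct = 100.0 * risk
    if pct < lower:
        category = "low_to_moderate"
    elif pct < upper:
        category = "high"
    else:
        category = "very_high"
    return TreatmentCategory(category=category, thresholds_used=(lower, upper))
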