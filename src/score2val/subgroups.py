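"""Study orchestration: stratified validation, pooling and sensitivity.

Runs the full external-validation pipeline over a raw cohort table:
cohort construction, multiple imputation, SCORE2 predictions for the
requested region models, calibration (OE-ratio) and discrimination
(Harrell's C) per stratum (sex x SES quintile x ethnicity), Rubin
pooling over imputations, best-fitting-region selection per stratum
(pooled OE nearest 1 on the log scale), treatment-eligibility shifts,
and the study's four sensitivity analyses.

Strata below the minimum-event gate are reported but carry no
estimates. Because recalibration is strictly monotone and every
stratum is sex-specific, Harrell's C is identical across the four
region models within a stratum and is computed once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from score2val.cohort import build_analysis_cohort
from score2val.engine import REGIONS, Score2ModelSpec, predict_risk_table
from score2val.impute import ImputationConfig, impute, rubin_pool
from score2val.metrics import harrells_c, min_events_gate, oe_ratio, calibration_curve

__all__ = [
    "StratumKey",
    "ValidationConfig",
    "SubgroupReport",
    "run_validation",
    "select_best_region",
    "eligibility_shift",
    "sensitivity_suite",
]

ALL = "all"


@dataclass(frozen=True)
class StratumKey:
    """A validation stratum; ``'all'`` marginalises a dimension."""

    sex: str
    ses_quintile: object = ALL  # int 1..5 or 'all'
    ethnicity: str = ALL

    def label(self) -> str:
        return f"{self.sex}|ses={self.ses_quintile}|eth={self.ethnicity}"


@dataclass(frozen=True)
class ValidationConfig:
    regions: tuple[str, ...] = REGIONS
    horizon: float = 10.0
    min_events: int = 200
    strata: tuple[str, ...] = ("sex", "sex_ses", "sex_ethnicity")
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    compute_curves: bool = False
    curve_bins: int = 10
    truncate_c: bool = True
    #: 'upper' classifies eligibility at the very-high-risk threshold,
    #: 'lower' at the treatment-consideration threshold.
    eligibility_threshold: str = "upper"

    def __post_init__(self) -> None:
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions {unknown}")
        if self.eligibility_threshold not in ("upper", "lower"):
            raise ValueError("eligibility_threshold must be 'upper' or 'lower'")


@dataclass
class SubgroupReport:
    results: pd.DataFrame
    best_region: dict
    eligibility: dict
    flowchart: dict
    curves: dict
    n: int

    def to_json(self) -> str:
        payload = {
            "n": self.n,
            "flowchart": self.flowchart,
            "results": json.loads(self.results.to_json(orient="records", double_precision=12)),
            "best_region": {k.label(): v for k, v in self.best_region.items()},
            "eligibility": self.eligibility,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _strata_for(analysis: pd.DataFrame, dims: tuple[str, ...]) -> list[StratumKey]:
    sexes = sorted(analysis["sex"].dropna().unique())
    eths = sorted(analysis["ethnicity"].dropna().unique()) if "ethnicity" in analysis else []
    out: list[StratumKey] = []
    for dim in dims:
        if dim == "sex":
            out += [StratumKey(s) for s in sexes]
        elif dim == "sex_ses":
            out += [StratumKey(s, q) for s in sexes for q in range(1, 6)]
        elif dim == "sex_ethnicity":
            out += [StratumKey(s, ALL, e) for s in sexes for e in eths]
        elif dim == "sex_ses_ethnicity":
            out += [StratumKey(s, q, e) for s in sexes for q in range(1, 6) for e in eths]
        else:
            raise ValueError(f"unknown stratum dimension {dim!r}")
    return out


def _stratum_mask(df: pd.DataFrame, key: StratumKey) -> np.ndarray:
    mask = (df["sex"] == key.sex).to_numpy()
    if key.ses_quintile != ALL:
        mask &= (df["ses_quintile"] == key.ses_quintile).to_numpy()
    if key.ethnicity != ALL:
        mask &= (df["ethnicity"] == key.ethnicity).to_numpy()
    return mask


def select_best_region(oe_by_region: Mapping[str, float]) -> str:
    """Region whose OE is nearest 1 on the log scale; ties go low."""
    if not oe_by_region:
        raise ValueError("need at least one region OE")
    best, best_val = None, np.inf
    for region in REGIONS:  # fixed order implements the lower-risk tie-break
        if region not in oe_by_region:
            continue
        val = abs(np.log(oe_by_region[region]))
        if val < best_val - 1e-12:
            best, best_val = region, val
    return best


def _upper_threshold(age: np.ndarray, which: str) -> np.ndarray:
    if which == "upper":
        return np.where(age < 50.0, 0.075, 0.10)
    return np.where(age < 50.0, 0.025, 0.05)


def eligibility_shift(
    pred_low: np.ndarray,
    pred_assigned: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    threshold: str = "upper",
) -> dict:
    """Percent of each sex at/above the treatment threshold, before/after.

    'Before' uses the low-risk model everywhere; 'after' the per-stratum
    assigned models. Thresholds are age-specific (2.5/7.5% under 50,
    5/10% otherwise); ``threshold`` picks which cut-off of the pair.
    """
    thr = _upper_threshold(np.asarray(age, dtype=float), threshold)
    out = {}
    for s in np.unique(sex):
        m = sex == s
        out[str(s)] = {
            "before_pct": float(100.0 * (pred_low[m] >= thr[m]).mean()),
            "after_pct": float(100.0 * (pred_assigned[m] >= thr[m]).mean()),
        }
    return out


def run_validation(
    cohort: pd.DataFrame,
    specs: Mapping[str, Score2ModelSpec],
    config: ValidationConfig = ValidationConfig(),
    row_filter: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> SubgroupReport:
    """Full pipeline: build cohort, impute, predict, validate, pool.

    ``row_filter`` optionally restricts the analysis cohort after
    follow-up classification (used by the sensitivity analyses).
    Deterministic for fixed inputs and imputation seed.
    """
    analysis, flowchart = build_analysis_cohort(cohort)
    if row_filter is not None:
        keep = np.asarray(row_filter(analysis), dtype=bool)
        flowchart = dict(flowchart, filtered_to=int(keep.sum()))
        analysis = analysis[keep].reset_index(drop=True)
    else:
        analysis = analysis.reset_index(drop=True)
    if not len(analysis):
        raise ValueError("no records remain after cohort construction")
    analysis = analysis.assign(age=analysis["age_entry"])

    completed = impute(analysis, config.imputation)
    m = len(completed)

    # per-imputation predictions, low first (also reused for C/eligibility)
    preds: list[dict[str, np.ndarray]] = []
    for comp in completed:
        frame = pd.DataFrame(
            {
                "age": comp["age_entry"],
                "sex": comp["sex"],
                "smoking": comp["smoking"],
                "sbp": comp["sbp"],
                "tchol": comp["tchol"],
                "hdl": comp["hdl"],
            }
        )
        preds.append(
            {r: predict_risk_table(frame, specs, region=r) for r in set(config.regions) | {"low"}}
        )

    strata = _strata_for(analysis, config.strata)
    time_arr = analysis["time"].to_numpy(dtype=float)
    status = analysis["status"].to_numpy()
    code = np.where(status == "cvd_event", 1, np.where(status == "competing_death", 2, 0))

    rows = []
    best: dict[StratumKey, str] = {}
    curves: dict = {}
    for key in strata:
        masks = [_stratum_mask(comp, key) for comp in completed]
        ev_counts = [int(((code == 1) & (time_arr <= config.horizon) & mk).sum()) for mk in masks]
        evaluable = min_events_gate(min(ev_counts), config.min_events)
        base = {
            "sex": key.sex,
            "ses_quintile": key.ses_quintile,
            "ethnicity": key.ethnicity,
            "n": int(np.mean([mk.sum() for mk in masks])),
            "events": int(np.mean(ev_counts)),
            "evaluable": evaluable,
        }
        if not evaluable:
            for region in config.regions:
                rows.append({**base, "region": region, "oe": np.nan, "oe_lo": np.nan,
                             "oe_hi": np.nan, "c": np.nan, "c_lo": np.nan, "c_hi": np.nan,
                             "observed_risk": np.nan, "mean_pred": np.nan})
            continue
        # C once per stratum (monotone-invariant across regions within a sex)
        c_est = []
        for d in range(m):
            mk = masks[d]
            res = harrells_c(
                time_arr[mk],
                (code[mk] == 1).astype(int),
                preds[d]["low"][mk],
                horizon=config.horizon if config.truncate_c else None,
            )
            c_est.append((res.c_statistic, res.se**2))
        c_pool = rubin_pool(c_est, scale="identity")
        oe_by_region: dict[str, float] = {}
        for region in config.regions:
            oe_est, obs_acc, pred_acc = [], 0.0, 0.0
            for d in range(m):
                mk = masks[d]
                cal = oe_ratio(time_arr[mk], code[mk], preds[d][region][mk], config.horizon)
                oe_est.append((cal.oe_ratio, cal.observed_risk_var / cal.observed_risk_10y**2
                               * cal.oe_ratio**2 if cal.observed_risk_10y > 0 else 0.0))
                obs_acc += cal.observed_risk_10y / m
                pred_acc += cal.mean_predicted / m
            oe_pool = rubin_pool(oe_est, scale="log")
            oe_by_region[region] = oe_pool.point
            rows.append(
                {
                    **base,
                    "region": region,
                    "oe": oe_pool.point,
                    "oe_lo": oe_pool.ci[0],
                    "oe_hi": oe_pool.ci[1],
                    "c": c_pool.point,
                    "c_lo": c_pool.ci[0],
                    "c_hi": c_pool.ci[1],
                    "observed_risk": obs_acc,
                    "mean_pred": pred_acc,
                }
            )
            if config.compute_curves and region == "low":
                mk = masks[0]
                curves[key.label()] = calibration_curve(
                    time_arr[mk], code[mk], preds[0]["low"][mk],
                    horizon=config.horizon, bins=config.curve_bins,
                )
        best[key] = select_best_region(oe_by_region)

    results = pd.DataFrame(rows)

    # eligibility under the low model vs the best-region assignment,
    # averaged over imputations (most specific stratum key wins)
    def assigned_region(sex, ses, eth) -> str:
        for k in (
            StratumKey(sex, ses, eth),
            StratumKey(sex, ses, ALL),
            StratumKey(sex, ALL, eth),
            StratumKey(sex, ALL, ALL),
        ):
            if k in best:
                return best[k]
        return "low"

    age = analysis["age_entry"].to_numpy(dtype=float)
    sex_arr = analysis["sex"].to_numpy()
    elig_acc: dict[str, dict[str, float]] = {}
    for d in range(m):
        comp = completed[d]
        regions_assigned = np.array(
            [
                assigned_region(s, q if q == q else ALL, e)
                for s, q, e in zip(comp["sex"], comp["ses_quintile"], comp["ethnicity"])
            ]
        )
        pred_assigned = preds[d]["low"].copy()
        for region in np.unique(regions_assigned):
            if region == "low" or region not in preds[d]:
                continue
            mask = regions_assigned == region
            pred_assigned[mask] = preds[d][region][mask]
        shift = eligibility_shift(
            preds[d]["low"], pred_assigned, age, sex_arr, config.eligibility_threshold
        )
        for s, vals in shift.items():
            acc = elig_acc.setdefault(s, {"before_pct": 0.0, "after_pct": 0.0})
            acc["before_pct"] += vals["before_pct"] / m
            acc["after_pct"] += vals["after_pct"] / m

    return SubgroupReport(
        results=results,
        best_region=best,
        eligibility=elig_acc,
        flowchart=flowchart,
        curves=curves,
        n=len(analysis),
    )


def sensitivity_suite(
    cohort: pd.DataFrame,
    specs: Mapping[str, Score2ModelSpec],
    config: ValidationConfig | None = None,
) -> dict:
    """The study's four sensitivity analyses.

    1. restrict to persons with at least one real measurement;
    2. restrict to the urban subarea, with SES imputed vs complete-SES only;
    3. age strata 40-50 and 50-70 (thresholds follow age automatically);
    4. outcome proxy: share of nonfatal CVD-event cases starting the
       statin + antithrombotic combination.
    """
    if config is None:
        config = ValidationConfig(regions=("low",), strata=("sex",))

    def summarise(report: SubgroupReport) -> dict:
        rows = report.results[report.results["region"] == "low"]
        return {
            r["sex"]: {"oe": r["oe"], "oe_ci": [r["oe_lo"], r["oe_hi"]],
                       "c": r["c"], "n": int(r["n"]), "events": int(r["events"])}
            for _, r in rows.iterrows()
            if r["ses_quintile"] == ALL and r["ethnicity"] == ALL
        }

    out: dict = {}

    measured = cohort[["sbp", "tchol", "hdl"]].notna().any(axis=1)
    out["measured_subset"] = summarise(
        run_validation(cohort[measured].reset_index(drop=True), specs, config)
    )

    if "subarea" in cohort:
        sub = cohort[cohort["subarea"].fillna(False).astype(bool)].reset_index(drop=True)
        out["subarea"] = {
            "ses_imputed": summarise(run_validation(sub, specs, config)),
            "ses_complete_only": summarise(
                run_validation(
                    sub[sub["ses_quintile"].notna()].reset_index(drop=True), specs, config
                )
            ),
        }

    out["age_strata"] = {
        "40_50": summarise(
            run_validation(cohort, specs, config, row_filter=lambda a: a["age_entry"] < 50)
        ),
        "50_70": summarise(
            run_validation(cohort, specs, config, row_filter=lambda a: a["age_entry"] >= 50)
        ),
    }

    nonfatal = cohort["cvd_event_date"].notna()
    proxy = cohort.loc[nonfatal, "med_proxy_start"].fillna(False).astype(bool)
    out["medication_proxy"] = {
        "n_events": int(nonfatal.sum()),
        "fraction_with_proxy": float(proxy.mean()) if nonfatal.any() else np.nan,
    }
    return out
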