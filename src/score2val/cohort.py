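"""Person-level cohort data model and study-cohort construction.

Covers the reconstruction of a dynamic primary-care cohort from raw
records: cohort-entry determination (latest of registration, study
start, 40th birthday), eligibility exclusions (prior CVD, diabetes,
statin/diabetes medication before entry, short registration),
outcome/competing-event classification with administrative, age-80
and deregistration censoring, baseline-nearest measurement selection,
and a validated CSV round trip.

Event coding follows the primary-care/mortality conventions of the
study: CVD death by ICD-10 chapter-I code prefixes with listed
exceptions, first CVD event by ICPC K75/K90 (except K90.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STUDY_START",
    "ADMIN_END",
    "EventCodeMap",
    "FollowUpOutcome",
    "determine_entry",
    "apply_exclusions",
    "classify_follow_up",
    "baseline_measurement",
    "build_analysis_cohort",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

STUDY_START = pd.Timestamp("2007-01-01")
ADMIN_END = pd.Timestamp("2020-07-01")
DAYS_PER_YEAR = 365.25  # epidemiological convention for person-years

_SEX_LABELS = {"male", "female"}
_ETH_LABELS = {"dutch", "surinamese", "other"}
_DEATH_CAUSES = {"cvd", "non_cvd"}
_SMOKING_SOURCES = {"coded", "text_mined", "assumed_nonsmoker"}
_MEAS_SOURCES = {"GP", "hospital"}

# (name, kind, required) — kind drives parsing/validation.
COHORT_COLUMNS: tuple[tuple[str, str, bool], ...] = (
    ("person_id", "str", True),
    ("sex", "sex", True),
    ("birth_date", "date", True),
    ("registration_start", "date", True),
    ("registration_end", "date", False),
    ("ethnicity", "ethnicity", False),
    ("ethnicity_detail", "str", False),
    ("ses_quintile", "quintile", False),
    ("smoking", "bool", False),
    ("smoking_source", "smoking_source", False),
    ("sbp", "float", False),
    ("sbp_date", "date", False),
    ("sbp_source", "meas_source", False),
    ("tchol", "float", False),
    ("tchol_date", "date", False),
    ("tchol_source", "meas_source", False),
    ("hdl", "float", False),
    ("hdl_date", "date", False),
    ("hdl_source", "meas_source", False),
    ("glucose", "float", False),
    ("egfr", "float", False),
    ("prior_cvd", "bool", False),
    ("diabetes", "bool", False),
    ("statin_use", "bool", False),
    ("diabetes_medication", "bool", False),
    ("cvd_event_date", "date", False),
    ("death_date", "date", False),
    ("death_cause", "death_cause", False),
    ("med_proxy_start", "bool", False),
    ("subarea", "bool", False),
)


@dataclass(frozen=True)
class EventCodeMap:
    """ICD-10 / ICPC code lists defining the endpoint and exclusions.

    Codes match by prefix; exception codes are excluded even when a
    prefix matches (e.g. I62.0 within I61–I65).
    """

    cvd_death_icd10: tuple[str, ...] = (
        "I10", "I11", "I12", "I13", "I14", "I15", "I16", "I17", "I18", "I19",
        "I20", "I21", "I22", "I23", "I24", "I25", "R96", "I46", "I47", "I48",
        "I49", "I50", "I51", "I61", "I62", "I63", "I64", "I65", "G45", "I67",
        "I68", "I69", "I70", "I71", "I72",
    )
    cvd_death_exceptions: tuple[str, ...] = ("I62.0", "I67.1")
    cvd_event_icpc: tuple[str, ...] = ("K75", "K90")
    cvd_event_exceptions: tuple[str, ...] = ("K90.1",)

    def __post_init__(self) -> None:
        if not self.cvd_death_icd10 or not self.cvd_event_icpc:
            raise ValueError("code lists must be non-empty")

    def is_cvd_death(self, code: str) -> bool:
        code = code.strip().upper()
        if any(code.startswith(exc) for exc in self.cvd_death_exceptions):
            return False
        return any(code.startswith(c) for c in self.cvd_death_icd10)

    def is_cvd_event(self, code: str) -> bool:
        code = code.strip().upper()
        if any(code.startswith(exc) for exc in self.cvd_event_exceptions):
            return False
        return any(code.startswith(c) for c in self.cvd_event_icpc)


@dataclass(frozen=True)
class FollowUpOutcome:
    time: float  # years from entry
    status: str  # cvd_event | competing_death | censored
    censor_reason: str | None = None  # age_80 | admin_end | deregistration

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("follow-up time must be positive")
        if self.status == "censored" and self.censor_reason is None:
            raise ValueError("censored outcomes need a reason")
        if self.status != "censored" and self.censor_reason is not None:
            raise ValueError("only censored outcomes carry a reason")


def _years_between(later: pd.Series, earlier: pd.Series) -> pd.Series:
    return (later - earlier).dt.days / DAYS_PER_YEAR


def _birthday(birth: pd.Series, years: int) -> pd.Series:
    # nth birthday; DateOffset handles leap days (Feb 29 -> Feb 28).
    return birth + pd.DateOffset(years=years)


def determine_entry(
    df: pd.DataFrame,
    study_start: pd.Timestamp = STUDY_START,
    study_end: pd.Timestamp = ADMIN_END,
) -> pd.DataFrame:
    """Cohort entry date and date-eligibility for each record.

    Entry is the latest of registration start, study start and the 40th
    birthday. Records are ineligible when entry falls at/after the 70th
    birthday, the registration end or the study end, or when dates are
    inconsistent (registration end before start).

    Returns a frame with ``entry_date`` and ``entry_reject_reason``
    (empty string when eligible).
    """
    birth = df["birth_date"]
    reg_start = df["registration_start"]
    reg_end = df.get("registration_end")
    if reg_end is None:
        reg_end = pd.Series(pd.NaT, index=df.index)

    entry = reg_start.copy()
    entry = entry.where(entry >= study_start, study_start)
    b40 = _birthday(birth, 40)
    entry = entry.where(entry >= b40, b40)
    b70 = _birthday(birth, 70)

    reason = pd.Series("", index=df.index, dtype=object)
    bad_dates = reg_end.notna() & (reg_end < reg_start)
    reason[bad_dates & (reason == "")] = "inconsistent_dates"
    reason[(entry >= b70) & (reason == "")] = "age_at_entry"
    reason[(entry >= study_end) & (reason == "")] = "entry_after_study_end"
    ended = reg_end.notna() & (entry >= reg_end)
    reason[ended & (reason == "")] = "registration_ended"
    return pd.DataFrame({"entry_date": entry, "entry_reject_reason": reason})


def apply_exclusions(df: pd.DataFrame, entry: pd.DataFrame | None = None) -> pd.Series:
    """Eligibility exclusions; returns a reason string per row ('' = keep).

    Drops: date-ineligible records (from :func:`determine_entry`), prior
    CVD, diabetes, statin or diabetes-medication use before entry, and
    registrations spanning under 6 months. History flags are
    assumed-absent when missing.
    """
    if entry is None:
        entry = determine_entry(df)
    reason = entry["entry_reject_reason"].copy()

    def flag(col: str) -> pd.Series:
        if col not in df:
            return pd.Series(False, index=df.index)
        return df[col].astype("boolean").fillna(False).astype(bool)

    for col, tag in (
        ("prior_cvd", "prior_cvd"),
        ("diabetes", "prior_diabetes"),
        ("statin_use", "statin_use"),
        ("diabetes_medication", "diabetes_medication"),
    ):
        reason[flag(col) & (reason == "")] = tag

    reg_end = df.get("registration_end")
    if reg_end is not None:
        span_days = (reg_end - df["registration_start"]).dt.days
        short = reg_end.notna() & (span_days < 182)
        reason[short & (reason == "")] = "short_registration"
    return reason


def classify_follow_up(
    df: pd.DataFrame,
    entry_date: pd.Series,
    admin_end: pd.Timestamp = ADMIN_END,
) -> pd.DataFrame:
    """Follow-up time and status for eligible records (vectorised).

    First-occurring of CVD event / CVD death is the endpoint; a first
    non-CVD death is the competing event; otherwise the person is
    censored at the earliest of the 80th birthday, the administrative
    study end and deregistration. A CVD event on the death date takes
    precedence (the combined endpoint counts either, once).

    Returns columns ``time`` (years), ``status`` and ``censor_reason``.
    """
    n = len(df)
    birth = df["birth_date"]
    reg_end = df.get("registration_end")
    if reg_end is None:
        reg_end = pd.Series(pd.NaT, index=df.index)
    event_date = df.get("cvd_event_date", pd.Series(pd.NaT, index=df.index))
    death_date = df.get("death_date", pd.Series(pd.NaT, index=df.index))
    death_cause = df.get("death_cause", pd.Series(pd.NA, index=df.index))

    if ((event_date.notna()) & (event_date < entry_date)).any() or (
        (death_date.notna()) & (death_date < entry_date)
    ).any():
        raise ValueError("terminating event before cohort entry; exclude upstream")

    b80 = _birthday(birth, 80)
    censor = pd.concat(
        [b80, pd.Series(admin_end, index=df.index), reg_end], axis=1
    ).min(axis=1)
    # reason priority for exact ties: age_80, admin_end, deregistration
    reason = np.where(
        censor == b80, "age_80", np.where(censor == admin_end, "admin_end", "deregistration")
    )

    cvd_date = event_date.copy()
    death_is_cvd = death_date.notna() & (death_cause == "cvd")
    use_death = death_is_cvd & (cvd_date.isna() | (death_date < cvd_date))
    cvd_date = cvd_date.where(~use_death, death_date)
    competing_date = death_date.where(death_date.notna() & (death_cause == "non_cvd"), pd.NaT)

    has_cvd = cvd_date.notna() & (cvd_date <= censor)
    has_comp = competing_date.notna() & (competing_date <= censor)
    cvd_first = has_cvd & (~has_comp | (cvd_date <= competing_date))
    comp_first = has_comp & ~cvd_first

    terminal = censor.copy()
    terminal = terminal.where(~cvd_first, cvd_date)
    terminal = terminal.where(~comp_first, competing_date)
    status = np.where(cvd_first, "cvd_event", np.where(comp_first, "competing_death", "censored"))
    reason = np.where(status == "censored", reason, "")

    time = _years_between(terminal, entry_date)
    if (time < 0).any():
        raise ValueError("terminal date before entry")
    # same-day terminal events get a nominal half day of follow-up
    time = time.where(time > 0, 0.5 / DAYS_PER_YEAR)
    return pd.DataFrame(
        {"time": time, "status": status, "censor_reason": reason}, index=df.index
    )


def baseline_measurement(
    candidates: Sequence[tuple[float, pd.Timestamp, str]] | pd.DataFrame,
    entry_date: pd.Timestamp,
    window_days: int = 365,
) -> float | None:
    """Select the baseline value from candidate (value, date, source) rows.

    GP measurements are preferred over hospital ones; within a source the
    latest value at/before entry wins, falling back to the earliest value
    after entry within ``window_days``.
    """
    if isinstance(candidates, pd.DataFrame):
        rows = list(candidates[["value", "date", "source"]].itertuples(index=False))
    else:
        rows = list(candidates)
    entry_date = pd.Timestamp(entry_date)
    for source in ("GP", "hospital"):
        sub = [(v, pd.Timestamp(d)) for v, d, s in rows if s == source and pd.notna(v)]
        if not sub:
            continue
        before = [(v, d) for v, d in sub if d <= entry_date]
        if before:
            return max(before, key=lambda t: t[1])[0]
        after = [
            (v, d) for v, d in sub if 0 < (d - entry_date).days <= window_days
        ]
        if after:
            return min(after, key=lambda t: t[1])[0]
    return None


def build_analysis_cohort(
    df: pd.DataFrame, admin_end: pd.Timestamp = ADMIN_END
) -> tuple[pd.DataFrame, dict]:
    """Run entry determination, exclusions and follow-up classification.

    Returns the analysis table (kept rows with ``entry_date``,
    ``age_entry``, ``time``, ``status``, ``censor_reason``, ``event``
    added; missing smoking resolved to non-smoking) and a flowchart dict
    whose drop reasons partition the dropped records.
    """
    entry = determine_entry(df, study_end=admin_end)
    reason = apply_exclusions(df, entry)
    kept = reason == ""
    flowchart = {
        "input": int(len(df)),
        "kept": int(kept.sum()),
        "dropped": {
            str(k): int(v) for k, v in reason[~kept].value_counts().sort_index().items()
        },
    }
    out = df[kept].copy()
    out["entry_date"] = entry.loc[kept, "entry_date"]
    out["age_entry"] = _years_between(out["entry_date"], out["birth_date"])
    fu = classify_follow_up(out, out["entry_date"], admin_end=admin_end)
    out[["time", "status", "censor_reason"]] = fu
    out["event"] = (out["status"] == "cvd_event").astype(int)
    if "smoking" in out:
        missing_smoking = out["smoking"].isna()
        out["smoking"] = out["smoking"].fillna(False).astype(bool)
        if "smoking_source" in out:
            out.loc[
                missing_smoking & out["smoking_source"].isna(), "smoking_source"
            ] = "assumed_nonsmoker"
    return out, flowchart


# ---------------------------------------------------------------------------
# CSV round trip with schema validation


class CohortSchemaError(ValueError):
    """CSV schema violation, carrying offending row numbers."""


def _validate(df: pd.DataFrame, strict_columns: bool = True) -> list[str]:
    errors: list[str] = []
    known = {c for c, _, _ in COHORT_COLUMNS}
    if strict_columns:
        unknown = set(df.columns) - known
        if unknown:
            errors.append(f"unknown columns: {sorted(unknown)}")
    for col, kind, required in COHORT_COLUMNS:
        if col not in df:
            if required:
                errors.append(f"missing required column: {col}")
            continue
        s = df[col]
        if required and s.isna().any():
            rows = list(df.index[s.isna()][:5])
            errors.append(f"column {col}: missing values at rows {rows}")
        bad = None
        if kind == "sex":
            bad = s.notna() & ~s.isin(list(_SEX_LABELS))
        elif kind == "ethnicity":
            bad = s.notna() & ~s.isin(list(_ETH_LABELS))
        elif kind == "death_cause":
            bad = s.notna() & ~s.isin(list(_DEATH_CAUSES))
        elif kind == "smoking_source":
            bad = s.notna() & ~s.isin(list(_SMOKING_SOURCES))
        elif kind == "meas_source":
            bad = s.notna() & ~s.isin(list(_MEAS_SOURCES))
        elif kind == "quintile":
            bad = s.notna() & ~s.isin([1, 2, 3, 4, 5, 1.0, 2.0, 3.0, 4.0, 5.0])
        if bad is not None and bad.any():
            rows = list(df.index[bad][:5])
            errors.append(
                f"column {col}: invalid values {sorted(set(s[bad].astype(str)))[:5]} at rows {rows}"
            )
    return errors


def _parse_types(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, kind, _ in COHORT_COLUMNS:
        if col not in out:
            continue
        if kind == "date":
            parsed = pd.to_datetime(out[col], format="%Y-%m-%d", errors="coerce")
            bad = out[col].notna() & (out[col].astype(str).str.len() > 0) & parsed.isna()
            if bad.any():
                rows = list(out.index[bad][:5])
                raise CohortSchemaError(f"column {col}: unparseable dates at rows {rows}")
            out[col] = parsed
        elif kind == "bool":
            out[col] = out[col].map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            )
            out[col] = out[col].astype("boolean")
        elif kind == "float":
            out[col] = pd.to_numeric(out[col], errors="raise")
        elif kind == "quintile":
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises with offending row numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    df = _parse_types(df)
    errors = _validate(df)
    if errors:
        raise CohortSchemaError("; ".join(errors))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (lossless round trip with read_cohort)."""
    errors = _validate(df, strict_columns=False)
    if errors:
        raise CohortSchemaError("; ".join(errors))
    out = df[[c for c, _, _ in COHORT_COLUMNS if c in df.columns]].copy()
    for col, kind, _ in COHORT_COLUMNS:
        if col in out and kind == "date":
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
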