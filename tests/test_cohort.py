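"""Cohort construction: entry, exclusions, follow-up, measurements, CSV."""

import numpy as np
import pandas as pd
import pytest

from score2val.cohort import (
    ADMIN_END,
    CohortSchemaError,
    EventCodeMap,
    FollowUpOutcome,
    apply_exclusions,
    baseline_measurement,
    build_analysis_cohort,
    classify_follow_up,
    determine_entry,
    read_cohort,
    write_cohort,
)


def _records(**overrides):
    base = dict(
        person_id="P1",
        sex="male",
        birth_date="1960-06-15",
        registration_start="2000-01-01",
        registration_end="2025-01-01",
        prior_cvd=False,
        diabetes=False,
        statin_use=False,
        diabetes_medication=False,
        cvd_event_date=pd.NaT,
        death_date=pd.NaT,
        death_cause=pd.NA,
    )
    base.update(overrides)
    df = pd.DataFrame([base])
    for c in ("birth_date", "registration_start", "registration_end",
              "cvd_event_date", "death_date"):
        df[c] = pd.to_datetime(df[c])
    return df


class TestDetermineEntry:
    def test_latest_of_rule_40th_birthday(self):
        df = _records(birth_date="1970-03-01", registration_start="2000-01-01")
        out = determine_entry(df)
        assert out["entry_date"].iloc[0] == pd.Timestamp("2010-03-01")
        assert out["entry_reject_reason"].iloc[0] == ""

    def test_registration_after_study_start(self):
        df = _records(birth_date="1950-01-01", registration_start="2012-05-01")
        out = determine_entry(df)
        assert out["entry_date"].iloc[0] == pd.Timestamp("2012-05-01")
        assert out["entry_reject_reason"].iloc[0] == ""

    def test_too_old_at_study_start_excluded(self):
        df = _records(birth_date="1936-01-01", registration_start="2007-01-01")
        out = determine_entry(df)
        assert out["entry_reject_reason"].iloc[0] == "age_at_entry"

    def test_inconsistent_dates_rejected(self):
        df = _records(registration_start="2010-01-01", registration_end="2009-01-01")
        out = determine_entry(df)
        assert out["entry_reject_reason"].iloc[0] == "inconsistent_dates"


class TestExclusions:
    def test_prior_cvd_dropped(self):
        assert apply_exclusions(_records(prior_cvd=True)).iloc[0] == "prior_cvd"

    def test_history_flags_assumed_absent_when_missing(self):
        df = _records()
        df["prior_cvd"] = pd.NA
        assert apply_exclusions(df).iloc[0] == ""

    def test_statin_after_entry_kept(self):
        # the flag encodes use *before* entry; a post-entry start is not flagged
        assert apply_exclusions(_records(statin_use=False)).iloc[0] == ""

    def test_short_registration_dropped(self):
        df = _records(registration_start="2010-01-01", registration_end="2010-06-01")
        assert apply_exclusions(df).iloc[0] == "short_registration"

    def test_six_months_exactly_kept(self):
        df = _records(registration_start="2010-01-01", registration_end="2010-07-02")
        assert apply_exclusions(df).iloc[0] == ""


class TestFollowUp:
    def test_first_event_wins_over_later_death(self):
        df = _records(
            registration_start="2008-01-01",
            cvd_event_date="2013-01-01",
            death_date="2015-01-01",
            death_cause="non_cvd",
        )
        entry = determine_entry(df)["entry_date"]
        out = classify_follow_up(df, entry)
        assert out["status"].iloc[0] == "cvd_event"
        assert out["time"].iloc[0] == pytest.approx(5.0, abs=0.01)

    def test_admin_censoring_at_study_end(self):
        df = _records(birth_date="1962-01-01", registration_start="2007-07-01")
        entry = determine_entry(df)["entry_date"]
        out = classify_follow_up(df, entry)
        assert out["status"].iloc[0] == "censored"
        assert out["censor_reason"].iloc[0] == "admin_end"
        assert out["time"].iloc[0] == pytest.approx(13.0, abs=0.01)

    def test_age_80_censoring(self):
        # entered at 69.5: censored at the 80th birthday, 10.5 years later
        df = _records(birth_date="1940-01-01", registration_start="2009-07-01",
                      registration_end="2030-01-01")
        entry = determine_entry(df)["entry_date"]
        assert determine_entry(df)["entry_reject_reason"].iloc[0] == ""
        out = classify_follow_up(df, entry, admin_end=pd.Timestamp("2025-07-01"))
        assert out["status"].iloc[0] == "censored"
        assert out["censor_reason"].iloc[0] == "age_80"
        assert out["time"].iloc[0] == pytest.approx(10.5, abs=0.01)

    def test_cvd_death_is_endpoint(self):
        df = _records(registration_start="2008-01-01",
                      death_date="2012-01-01", death_cause="cvd")
        entry = determine_entry(df)["entry_date"]
        out = classify_follow_up(df, entry)
        assert out["status"].iloc[0] == "cvd_event"

    def test_competing_death(self):
        df = _records(registration_start="2008-01-01",
                      death_date="2012-01-01", death_cause="non_cvd")
        entry = determine_entry(df)["entry_date"]
        out = classify_follow_up(df, entry)
        assert out["status"].iloc[0] == "competing_death"

    def test_event_before_entry_raises(self):
        df = _records(registration_start="2008-01-01", cvd_event_date="2007-06-01")
        entry = determine_entry(df)["entry_date"]
        with pytest.raises(ValueError, match="before cohort entry"):
            classify_follow_up(df, entry)

    def test_outcome_dataclass_consistency(self):
        with pytest.raises(ValueError):
            FollowUpOutcome(time=1.0, status="censored", censor_reason=None)
        with pytest.raises(ValueError):
            FollowUpOutcome(time=-1.0, status="cvd_event")
        FollowUpOutcome(time=2.5, status="censored", censor_reason="age_80")


class TestEventCodeMap:
    def test_exception_codes_excluded(self):
        codes = EventCodeMap()
        assert codes.is_cvd_death("I21.0")
        assert codes.is_cvd_death("I62.9")
        assert not codes.is_cvd_death("I62.0")
        assert not codes.is_cvd_death("I67.1")
        assert codes.is_cvd_event("K75")
        assert codes.is_cvd_event("K90.2")
        assert not codes.is_cvd_event("K90.1")
        assert not codes.is_cvd_event("A01")

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            EventCodeMap(cvd_death_icd10=())


class TestBaselineMeasurement:
    ENTRY = pd.Timestamp("2010-01-01")

    def test_gp_preferred_over_nearer_hospital(self):
        value = baseline_measurement(
            [(140.0, pd.Timestamp("2009-12-02"), "GP"),
             (150.0, pd.Timestamp("2009-12-31"), "hospital")],
            self.ENTRY,
        )
        assert value == 140.0

    def test_before_preferred_over_nearer_after(self):
        value = baseline_measurement(
            [(120.0, pd.Timestamp("2009-12-22"), "GP"),
             (130.0, pd.Timestamp("2010-01-03"), "GP")],
            self.ENTRY,
        )
        assert value == 120.0

    def test_window_excludes_late_values(self):
        assert baseline_measurement(
            [(120.0, pd.Timestamp("2011-02-05"), "GP")], self.ENTRY, window_days=365
        ) is None

    def test_fallback_to_post_entry_within_window(self):
        assert baseline_measurement(
            [(120.0, pd.Timestamp("2010-06-01"), "GP")], self.ENTRY
        ) == 120.0


class TestCsvRoundTrip:
    def test_round_trip_lossless(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        head = cohort.head(100).reset_index(drop=True)
        path = tmp_path / "cohort.csv"
        write_cohort(head, path)
        back = read_cohort(path)
        for col in head.columns:
            a, b = head[col], back[col]
            if a.dtype.kind == "f":
                assert np.allclose(a.fillna(-1), b.fillna(-1))
            else:
                a_norm = a.where(a.notna(), None).astype(object).astype(str)
                b_norm = b.where(b.notna(), None).astype(object).astype(str)
                assert (a_norm == b_norm).all(), col

    def test_invalid_sex_names_row(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        head = cohort.head(5).reset_index(drop=True).copy()
        head.loc[3, "sex"] = "X"
        path = tmp_path / "bad.csv"
        head.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match=r"sex.*\[3\]"):
            read_cohort(path)

    def test_required_columns_only(self, tmp_path):
        path = tmp_path / "minimal.csv"
        path.write_text(
            "person_id,sex,birth_date,registration_start\n"
            "A1,female,1965-04-01,2006-01-01\n"
        )
        df = read_cohort(path)
        assert df["person_id"].iloc[0] == "A1"

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "person_id,sex,birth_date,registration_start,shoe_size\n"
            "A1,female,1965-04-01,2006-01-01,42\n"
        )
        with pytest.raises(CohortSchemaError, match="shoe_size"):
            read_cohort(path)


class TestFlowchart:
    def test_reasons_partition_dropped(self, small_cohort):
        cohort, _ = small_cohort
        raw = cohort.copy()
        # inject excludable records
        raw.loc[raw.index[:30], "prior_cvd"] = True
        raw.loc[raw.index[30:50], "diabetes"] = True
        _, flow = build_analysis_cohort(raw)
        assert flow["kept"] + sum(flow["dropped"].values()) == flow["input"] == len(raw)
        assert flow["dropped"]["prior_cvd"] == 30
        assert flow["dropped"]["prior_diabetes"] == 20

    def test_follow_up_bounds(self, small_cohort):
        cohort, _ = small_cohort
        analysis, _ = build_analysis_cohort(cohort)
        assert (analysis["time"] <= 13.5 + 1e-6).all()
        assert (analysis["time"] <= 80.0 - analysis["age_entry"] + 0.01).all()
        assert (analysis["time"] > 0).all()
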