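"""Metric tests: Aalen–Johansen, OE-ratio, calibration curve, Harrell's C."""

import numpy as np
import pandas as pd
import pytest

from score2val.metrics import (
    aalen_johansen,
    calibration_curve,
    cumulative_incidence,
    harrells_c,
    min_events_gate,
    oe_ratio,
)

# six-subject worked fixture, stepped by hand through the estimator table:
# times 1..6 with statuses event, competing, censored, event, censored, event
SIX_T = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
SIX_C = [1, 2, 0, 1, 0, 1]


class TestAalenJohansen:
    def test_hand_stepped_six_subject_table(self):
        cif, _ = cumulative_incidence(SIX_T, SIX_C, 4.5)
        assert cif == pytest.approx(7.0 / 18.0, abs=1e-12)
        cif10, _ = cumulative_incidence(SIX_T, SIX_C, 10.0)
        assert cif10 == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_against_independent_competing_risk_oracle(self):
        """Frozen point estimates from an independent competing-risks
        implementation (R cmprsk::cuminc) on a 15-subject fixture."""
        t = [0.5, 1.1, 1.3, 2.0, 2.2, 2.9, 3.5, 4.1, 4.6, 5.0, 5.5, 6.2, 7.0, 8.5, 9.0]
        c = [1, 0, 2, 1, 0, 1, 2, 0, 1, 0, 2, 1, 0, 1, 0]
        curve = aalen_johansen(t, c)
        at = lambda h, col: curve[curve["time"] <= h][col].iloc[-1]
        assert at(5.0, "cif1") == pytest.approx(0.307692307692, abs=1e-9)
        assert at(9.0, "cif1") == pytest.approx(0.578461538462, abs=1e-9)
        assert at(5.0, "cif2") == pytest.approx(0.150769230769, abs=1e-9)
        assert at(9.0, "cif2") == pytest.approx(0.259076923077, abs=1e-9)

    def test_reduces_to_proportion_without_censoring(self):
        t = np.r_[np.linspace(1, 9, 20), np.full(80, 11.0)]
        c = np.r_[np.ones(20, int), np.zeros(80, int)]
        cif, var = cumulative_incidence(t, c, 10.0)
        assert cif == pytest.approx(0.20, abs=1e-12)

    def test_no_events_gives_zero(self):
        cif, var = cumulative_incidence([1.0, 2.0, 3.0], [0, 0, 0], 10.0)
        assert cif == 0.0 and var == 0.0

    def test_equals_one_minus_km_without_competing(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(5, 400)
        e = (rng.random(400) < 0.6).astype(int)
        km = KaplanMeierFitter().fit(t, e)
        for h in (1.0, 3.0, 7.0):
            cif, _ = cumulative_incidence(t, e, h)
            assert cif == pytest.approx(1 - km.predict(h), abs=1e-10)

    def test_variance_matches_lifelines(self, rng):
        from lifelines import AalenJohansenFitter

        t = rng.exponential(5, 300)
        c = rng.choice([0, 1, 2], size=300, p=[0.4, 0.35, 0.25])
        aj = AalenJohansenFitter(calculate_variance=True).fit(t, c, event_of_interest=1)
        cif, var = cumulative_incidence(t, c, 4.0)
        dens = aj.cumulative_density_
        ours = dens.index[dens.index <= 4.0]
        assert cif == pytest.approx(float(dens.iloc[len(ours) - 1, 0]), abs=1e-10)
        assert var == pytest.approx(float(aj.variance_.iloc[len(ours) - 1]), rel=1e-8)

    def test_state_occupation_sums_to_one(self, rng):
        t = rng.exponential(4, 500)
        c = rng.choice([0, 1, 2], size=500, p=[0.3, 0.4, 0.3])
        curve = aalen_johansen(t, c)
        total = curve["surv"] + curve["cif1"] + curve["cif2"]
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_cause_cif_below_all_cause_incidence(self, rng):
        t = rng.exponential(4, 500)
        c = rng.choice([0, 1, 2], size=500, p=[0.3, 0.4, 0.3])
        curve = aalen_johansen(t, c)
        all_cause = aalen_johansen(t, (np.asarray(c) > 0).astype(int))
        merged = pd.merge_asof(curve, all_cause, on="time", suffixes=("", "_all"))
        assert (merged["cif1"] <= merged["cif1_all"] + 1e-10).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cumulative_incidence([], [], 10.0)
        with pytest.raises(ValueError):
            cumulative_incidence([1.0], [3], 10.0)
        with pytest.raises(ValueError):
            cumulative_incidence([1.0], [1], 0.0)


class TestOERatio:
    def test_unity_when_observed_equals_mean_predicted(self):
        t = np.r_[np.linspace(1, 9, 30), np.full(70, 12.0)]
        c = np.r_[np.ones(30, int), np.zeros(70, int)]
        res = oe_ratio(t, c, np.full(100, 0.30))
        assert res.oe_ratio == pytest.approx(1.0, abs=1e-12)
        assert res.ci[0] < 1.0 < res.ci[1]

    def test_study_scale_uncensored_fixture(self):
        """6966 events observed vs 5495 predicted on an uncensored cohort:
        the ratio is forced to 6966/5495."""
        n, events, predicted = 155013, 6966, 5495
        t = np.r_[np.full(events, 5.0), np.full(n - events, 10.5)]
        c = np.r_[np.ones(events, int), np.zeros(n - events, int)]
        res = oe_ratio(t, c, np.full(n, predicted / n))
        assert res.oe_ratio == pytest.approx(events / predicted, rel=1e-12)
        assert res.observed_events == events
        assert res.oe_ratio == pytest.approx(1.268, abs=5e-4)

    def test_uncensored_equals_proportion_over_mean(self, rng):
        n = 500
        p = rng.uniform(0.02, 0.3, n)
        event = rng.random(n) < p
        t = np.where(event, rng.uniform(0.5, 9.5, n), 10.0 + rng.random(n))
        res = oe_ratio(t, event.astype(int), p)
        assert res.oe_ratio == pytest.approx(event.mean() / p.mean(), rel=1e-12)

    def test_designed_multiplier_recovery_with_censoring(self, rng):
        from score2val.simulate import _hazards_vec

        n = 40000
        pred = rng.uniform(0.02, 0.10, n)
        true = 1.5 * pred
        lam1, lam2 = _hazards_vec(true, np.full(n, 0.03), 10.0)
        t1 = rng.exponential(1.0, n) / lam1
        t2 = rng.exponential(1.0, n) / lam2
        censor = np.minimum(rng.exponential(30.0, n), 12.0)
        t = np.minimum.reduce([t1, t2, censor])
        code = np.where(t == censor, 0, np.where(t1 <= t2, 1, 2))
        res = oe_ratio(t, code, pred)
        assert res.ci[0] <= 1.5 <= res.ci[1]
        assert res.oe_ratio == pytest.approx(1.5, abs=0.1)

    def test_alignment_and_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            oe_ratio([1.0, 2.0], [1, 0], [0.1])
        with pytest.raises(ValueError):
            oe_ratio([1.0, 2.0], [1, 0], [0.0, 0.0])


class TestCalibrationCurve:
    def test_perfectly_calibrated_bins_near_identity(self, rng):
        n = 30000
        p = rng.uniform(0.01, 0.25, n)
        event = rng.random(n) < p
        t = np.where(event, rng.uniform(0.5, 9.9, n), 10.5)
        curve = calibration_curve(t, event.astype(int), p, bins=10)
        b = curve.bins
        se = (b["ci_hi"] - b["ci_lo"]) / (2 * 1.96)
        z = (b["observed"] - b["mean_predicted"]) / se
        assert (z.abs() < 3.5).all()
        assert b["mean_predicted"].is_monotonic_increasing
        assert b["n"].sum() == n

    def test_constant_predictions_merge_with_warning(self):
        t = np.r_[np.linspace(1, 9, 30), np.full(70, 12.0)]
        c = np.r_[np.ones(30, int), np.zeros(70, int)]
        with pytest.warns(UserWarning, match="distinct"):
            curve = calibration_curve(t, c, np.full(100, 0.3), bins=10)
        assert len(curve.bins) == 1

    def test_loess_slope_recovers_multiplier(self, rng):
        from score2val.simulate import _hazards_vec

        n = 60000
        pred = rng.uniform(0.02, 0.10, n)
        true = np.minimum(1.9 * pred, 0.9)
        lam1, lam2 = _hazards_vec(true, np.full(n, 0.03), 10.0)
        t1 = rng.exponential(1.0, n) / lam1
        t2 = rng.exponential(1.0, n) / lam2
        t = np.minimum(np.minimum(t1, t2), 11.0)
        code = np.where(t == 11.0, 0, np.where(t1 <= t2, 1, 2))
        curve = calibration_curve(t, code, pred)
        slope = np.polyfit(curve.loess["predicted"], curve.loess["observed"], 1)[0]
        assert slope == pytest.approx(1.9, abs=0.2)


class TestHarrellsC:
    def test_constant_predictions_give_half(self, rng):
        t = rng.exponential(5, 50)
        e = np.ones(50, int)
        res = harrells_c(t, e, np.full(50, 0.2), horizon=None)
        assert res.c_statistic == pytest.approx(0.5)

    def test_perfect_ranking_gives_one(self, rng):
        t = np.sort(rng.exponential(5, 80))
        res = harrells_c(t, np.ones(80, int), -t, horizon=None)
        assert res.c_statistic == 1.0
        assert res.comparable_pairs == 80 * 79 // 2

    def test_matches_brute_force_oracle(self, rng):
        n = 300
        t = np.round(rng.exponential(5, n), 1)  # deliberate time ties
        e = (rng.random(n) < 0.6).astype(int)
        p = np.round(rng.random(n), 2)  # deliberate prediction ties
        res = harrells_c(t, e, p, horizon=None)
        conc = comp = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if (t[i] < t[j] and e[i] == 1) or (t[i] == t[j] and e[i] == 1 and e[j] == 0):
                    comp += 1
                    if p[i] > p[j]:
                        conc += 1
                    elif p[i] == p[j]:
                        conc += 0.5
        assert res.comparable_pairs == int(comp)
        assert res.c_statistic == pytest.approx(conc / comp, abs=1e-12)

    def test_matches_lifelines_on_continuous_data(self, rng):
        from lifelines.utils import concordance_index

        t = rng.exponential(5, 500)
        e = (rng.random(500) < 0.7).astype(int)
        p = rng.random(500)
        res = harrells_c(t, e, p, horizon=None)
        assert res.c_statistic == pytest.approx(concordance_index(t, -p, e), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        t = rng.exponential(5, 400)
        e = (rng.random(400) < 0.6).astype(int)
        p = rng.uniform(0.01, 0.5, 400)
        a = harrells_c(t, e, p)
        b = harrells_c(t, e, np.exp(3.0 * p) - 1.0)
        assert a.c_statistic == pytest.approx(b.c_statistic, abs=1e-14)
        assert a.comparable_pairs == b.comparable_pairs

    def test_horizon_truncation_censors_late_events(self):
        t = np.array([2.0, 12.0, 15.0])
        e = np.array([1, 1, 0])
        res = harrells_c(t, e, np.array([0.9, 0.5, 0.1]), horizon=10.0)
        # the two late subjects become censored at 10; only subject 0's event counts
        assert res.comparable_pairs == 2
        assert res.c_statistic == 1.0

    def test_variance_positive_and_ci_orders(self, rng):
        t = rng.exponential(5, 300)
        e = (rng.random(300) < 0.6).astype(int)
        p = rng.random(300)
        res = harrells_c(t, e, p)
        assert res.se > 0
        assert res.ci[0] < res.c_statistic < res.ci[1]

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrells_c([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestMinEventsGate:
    @pytest.mark.parametrize("n,ok", [(199, False), (200, True), (0, False), (1000, True)])
    def test_boundary(self, n, ok):
        assert min_events_gate(n) is ok


def test_stratified_oe_composition_consistency(rng):
    """Uncensored: overall observed and expected counts equal the sums of
    stratum counts, so the overall OE is the E-weighted stratum mean."""
    n = 3000
    strata = rng.integers(0, 3, n)
    p = rng.uniform(0.05, 0.4, n)
    event = rng.random(n) < np.minimum(1.4 * p, 0.9)
    t = np.where(event, rng.uniform(0.5, 9.5, n), 10.5)
    overall = oe_ratio(t, event.astype(int), p)
    o_sum = e_sum = 0.0
    for s in range(3):
        mk = strata == s
        res = oe_ratio(t[mk], event[mk].astype(int), p[mk])
        o_sum += res.observed_risk_10y * mk.sum()
        e_sum += res.mean_predicted * mk.sum()
    assert o_sum == pytest.approx(overall.observed_risk_10y * n, rel=1e-10)
    assert e_sum == pytest.approx(overall.mean_predicted * n, rel=1e-10)
    assert overall.oe_ratio == pytest.approx(o_sum / e_sum, rel=1e-10)
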