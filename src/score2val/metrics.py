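"""Fixed-horizon validation metrics under competing risks.

Observed risk is the Aalen–Johansen cumulative incidence of the event
of interest (non-CVD death competing, censoring non-informative), with
the standard counting-process variance. Calibration is summarised by
the OE-ratio (observed risk / mean predicted probability; CI by the
delta method on the log scale with the expected side treated as fixed)
and by decile calibration curves with a LOESS smooth. Discrimination is
Harrell's C over comparable pairs (competing deaths treated as
censoring at the death time), computed in O(n log n) with Fenwick
trees, with a pair-cluster (U-statistic) analytic variance.

Event coding throughout: 0 = censored, 1 = event of interest,
2 = competing event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "CalibrationResult",
    "CalibrationCurve",
    "DiscriminationResult",
    "aalen_johansen",
    "cumulative_incidence",
    "oe_ratio",
    "calibration_curve",
    "harrells_c",
    "min_events_gate",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class CalibrationResult:
    n: int
    observed_events: int
    observed_risk_10y: float
    observed_risk_var: float
    mean_predicted: float
    oe_ratio: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class CalibrationCurve:
    bins: pd.DataFrame  # mean_predicted, observed, ci_lo, ci_hi, n per bin
    loess: pd.DataFrame  # predicted, observed (smoothed)


@dataclass(frozen=True)
class DiscriminationResult:
    c_statistic: float
    ci: tuple[float, float]
    se: float
    comparable_pairs: int


def _check_codes(code: np.ndarray) -> None:
    if not np.isin(code, (0, 1, 2)).all():
        raise ValueError("event codes must be 0 (censored), 1 (event) or 2 (competing)")


def aalen_johansen(time, code) -> pd.DataFrame:
    """Aalen–Johansen estimate over all distinct event times.

    Returns a frame with columns ``time``, ``surv`` (overall event-free
    survival just after t), ``cif1``, ``cif2`` and ``var1`` (variance of
    the cause-1 CIF).
    """
    time = np.asarray(time, dtype=float)
    code = np.asarray(code, dtype=int)
    _check_codes(code)
    if len(time) == 0 or not (time > 0).any():
        raise ValueError("need at least one subject with positive follow-up")
    order = np.argsort(time, kind="stable")
    t, c = time[order], code[order]
    n = len(t)

    # aggregate per distinct time
    ut, idx = np.unique(t, return_index=True)
    grp = np.searchsorted(ut, t)
    d1 = np.bincount(grp, weights=(c == 1), minlength=len(ut))
    d2 = np.bincount(grp, weights=(c == 2), minlength=len(ut))
    atrisk = n - idx  # subjects with time >= ut[k]
    d = d1 + d2

    with np.errstate(divide="ignore", invalid="ignore"):
        km_factors = 1.0 - d / atrisk
    surv_before = np.concatenate([[1.0], np.cumprod(km_factors)[:-1]])  # S(t-)
    cif1 = np.cumsum(surv_before * d1 / atrisk)
    cif2 = np.cumsum(surv_before * d2 / atrisk)
    surv = np.cumprod(km_factors)

    # counting-process variance of cif1 (Marubini & Valsecchi form),
    # evaluated at every distinct event time T:
    #   sum_{k<=T} [ a_k^2 d_k/(n_k(n_k-d_k))
    #                + S(t_k-)^2 d1_k (n_k - d1_k)/n_k^3
    #                - 2 a_k S(t_k-) d1_k/n_k^2 ],  a_k = CIF1(T) - CIF1(t_k)
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = np.where(atrisk > d, d / (atrisk * (atrisk - d)), 0.0)
    g2 = surv_before**2 * d1 * (atrisk - d1) / atrisk**3
    g3 = surv_before * d1 / atrisk**2
    # cumulative pieces let the a_k terms be expanded without an inner loop
    c_g1 = np.cumsum(g1)
    c_g1f = np.cumsum(g1 * cif1)
    c_g1f2 = np.cumsum(g1 * cif1**2)
    c_g2 = np.cumsum(g2)
    c_g3 = np.cumsum(g3)
    c_g3f = np.cumsum(g3 * cif1)
    var1 = (
        cif1**2 * c_g1 - 2.0 * cif1 * c_g1f + c_g1f2
        + c_g2
        - 2.0 * (cif1 * c_g3 - c_g3f)
    )
    return pd.DataFrame(
        {"time": ut, "surv": surv, "cif1": cif1, "cif2": cif2, "var1": np.maximum(var1, 0.0)}
    )


def cumulative_incidence(time, code, horizon: float) -> tuple[float, float]:
    """Cause-1 cumulative incidence and its variance at ``horizon``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    curve = aalen_johansen(time, code)
    k = np.searchsorted(curve["time"].to_numpy(), horizon, side="right") - 1
    if k < 0:
        return 0.0, 0.0
    return float(curve["cif1"].iloc[k]), float(curve["var1"].iloc[k])


def oe_ratio(time, code, predictions, horizon: float = 10.0) -> CalibrationResult:
    """Observed/expected ratio at the horizon.

    Observed is the Aalen–Johansen cause-1 incidence; expected is the
    mean predicted probability. CI: ``exp(ln OE ± 1.96 sqrt(var_O)/O)``
    (expected treated as fixed).
    """
    predictions = np.asarray(predictions, dtype=float)
    time = np.asarray(time, dtype=float)
    code = np.asarray(code, dtype=int)
    if len(predictions) != len(time):
        raise ValueError("predictions must align with outcomes")
    e_mean = float(predictions.mean())
    if e_mean <= 0:
        raise ValueError("mean predicted probability must be positive")
    o, var_o = cumulative_incidence(time, code, horizon)
    oe = o / e_mean
    if o > 0:
        se_ln = np.sqrt(var_o) / o
        ci = (oe * np.exp(-_Z95 * se_ln), oe * np.exp(_Z95 * se_ln))
    else:
        ci = (0.0, np.inf)
    return CalibrationResult(
        n=len(time),
        observed_events=int(((code == 1) & (time <= horizon)).sum()),
        observed_risk_10y=o,
        observed_risk_var=var_o,
        mean_predicted=e_mean,
        oe_ratio=oe,
        ci=ci,
    )


def calibration_curve(
    time,
    code,
    predictions,
    horizon: float = 10.0,
    bins: int = 10,
    loess_span: float = 0.75,
    ids=None,
) -> CalibrationCurve:
    """Decile calibration curve with a LOESS smooth.

    The sample is split into ``bins`` equal-count groups by predicted
    risk (ties broken by a stable sort on (prediction, id)); each group
    contributes its mean prediction and Aalen–Johansen observed risk at
    the horizon. The LOESS curve smooths observed risk over a finer
    grid of prediction slices (weighted lowess, degree 1).
    """
    predictions = np.asarray(predictions, dtype=float)
    time = np.asarray(time, dtype=float)
    code = np.asarray(code, dtype=int)
    n = len(predictions)
    if n < bins:
        raise ValueError(f"need at least {bins} observations")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), predictions))
    n_distinct = len(np.unique(predictions))
    eff_bins = bins
    if n_distinct < bins:
        warnings.warn(
            f"only {n_distinct} distinct predictions; merging into {n_distinct} bin(s)",
            stacklevel=2,
        )
        eff_bins = max(n_distinct, 1)
    rows = []
    for chunk in np.array_split(order, eff_bins):
        o, var_o = cumulative_incidence(time[chunk], code[chunk], horizon)
        half = _Z95 * np.sqrt(var_o)
        rows.append(
            {
                "mean_predicted": float(predictions[chunk].mean()),
                "observed": o,
                "ci_lo": max(o - half, 0.0),
                "ci_hi": min(o + half, 1.0),
                "n": len(chunk),
            }
        )
    bins_df = pd.DataFrame(rows)

    from statsmodels.nonparametric.smoothers_lowess import lowess

    n_slices = min(max(3 * eff_bins, 20), max(n // 20, 1))
    xs, ys = [], []
    for chunk in np.array_split(order, n_slices):
        o, _ = cumulative_incidence(time[chunk], code[chunk], horizon)
        xs.append(float(predictions[chunk].mean()))
        ys.append(o)
    smoothed = lowess(ys, xs, frac=loess_span, it=0, return_sorted=True)
    loess_df = pd.DataFrame({"predicted": smoothed[:, 0], "observed": smoothed[:, 1]})
    return CalibrationCurve(bins=bins_df, loess=loess_df)


# ---------------------------------------------------------------------------
# Harrell's C


@njit(cache=False)
def _concordance_pass(order, time, event, rank, nrank):  # pragma: no cover - numba
    """One ascending sweep: per-subject late-side pair counts.

    For every subject j, counts pairs in which j is the later member:
    events strictly before t_j, plus events at t_j when j is censored.
    Returns (n_late, c_late) with prediction ties counting 1/2.
    """
    n = len(order)
    tree = np.zeros(nrank + 1, dtype=np.float64)
    total = 0.0
    n_late = np.zeros(n)
    c_late = np.zeros(n)
    i = 0
    while i < n:
        j = i
        t = time[order[i]]
        while j < n and time[order[j]] == t:
            j += 1
        # query all group members against earlier events
        for k in range(i, j):
            s = order[k]
            r = rank[s]
            le = 0.0
            rr = r
            while rr > 0:
                le += tree[rr]
                rr -= rr & (-rr)
            lt = 0.0
            rr = r - 1
            while rr > 0:
                lt += tree[rr]
                rr -= rr & (-rr)
            eq = le - lt
            gt = total - le
            n_late[s] += total
            c_late[s] += gt + 0.5 * eq
        # same-time event-vs-censored pairs (censored is the later member)
        for k in range(i, j):
            s = order[k]
            if event[s] != 0:
                continue
            for k2 in range(i, j):
                s2 = order[k2]
                if event[s2] != 1:
                    continue
                n_late[s] += 1.0
                if rank[s2] > rank[s]:
                    c_late[s] += 1.0
                elif rank[s2] == rank[s]:
                    c_late[s] += 0.5
        # insert this group's events
        for k in range(i, j):
            s = order[k]
            if event[s] == 1:
                rr = rank[s]
                while rr <= nrank:
                    tree[rr] += 1.0
                    rr += rr & (-rr)
                total += 1.0
        i = j
    return n_late, c_late


@njit(cache=False)
def _concordance_pass_desc(order, time, event, rank, nrank):  # pragma: no cover
    """Descending sweep: per-subject early-side counts for event subjects."""
    n = len(order)
    tree = np.zeros(nrank + 1, dtype=np.float64)
    total = 0.0
    n_early = np.zeros(n)
    c_early = np.zeros(n)
    i = n - 1
    while i >= 0:
        j = i
        t = time[order[i]]
        while j >= 0 and time[order[j]] == t:
            j -= 1
        # events in group (i..j+1 descending) vs strictly later subjects
        for k in range(j + 1, i + 1):
            s = order[k]
            if event[s] != 1:
                continue
            r = rank[s]
            le = 0.0
            rr = r
            while rr > 0:
                le += tree[rr]
                rr -= rr & (-rr)
            lt = 0.0
            rr = r - 1
            while rr > 0:
                lt += tree[rr]
                rr -= rr & (-rr)
            eq = le - lt
            n_early[s] += total
            c_early[s] += lt + 0.5 * eq
            # same-time censored partners
            for k2 in range(j + 1, i + 1):
                s2 = order[k2]
                if event[s2] != 0:
                    continue
                n_early[s] += 1.0
                if rank[s2] < r:
                    c_early[s] += 1.0
                elif rank[s2] == r:
                    c_early[s] += 0.5
        # insert all group members
        for k in range(j + 1, i + 1):
            s = order[k]
            rr = rank[s]
            while rr <= nrank:
                tree[rr] += 1.0
                rr += rr & (-rr)
            total += 1.0
        i = j
    return n_early, c_early


def harrells_c(
    time, event, predictions, horizon: float | None = 10.0
) -> DiscriminationResult:
    """Harrell's concordance for right-censored data.

    ``event`` is 1 for the event of interest; competing deaths must be
    coded 0 (censored at the death time) by the caller — pass
    ``(code == 1)``. With ``horizon`` set, follow-up is truncated there
    (events after the horizon count as censored) for consistency with
    fixed-horizon predictions.

    A comparable pair has the shorter time ending in an event (or equal
    times with exactly one event); it is concordant when the event
    subject carries the higher prediction, prediction ties count 1/2.
    The variance is the pair-cluster (U-statistic) estimator
    ``sum_j (s_j - C m_j)^2 / M^2`` over per-subject pair sums.
    """
    time = np.asarray(time, dtype=float).copy()
    event = np.asarray(event, dtype=int).copy()
    predictions = np.asarray(predictions, dtype=float)
    if len(time) < 2:
        raise ValueError("need at least two subjects")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be 0/1 (treat competing events as censored)")
    if horizon is not None:
        late = time > horizon
        time[late] = horizon
        event[late] = 0

    rank = pd.factorize(predictions, sort=True)[0] + 1
    nrank = int(rank.max())
    order = np.argsort(time, kind="stable").astype(np.int64)
    n_late, c_late = _concordance_pass(order, time, event, rank.astype(np.int64), nrank)
    n_early, c_early = _concordance_pass_desc(
        order, time, event, rank.astype(np.int64), nrank
    )
    m_pairs = float(n_late.sum())
    if m_pairs == 0:
        raise ValueError("no comparable pairs")
    c_stat = float(c_late.sum() / m_pairs)
    s = c_late + c_early
    m = n_late + n_early
    var = float(((s - c_stat * m) ** 2).sum() / m_pairs**2)
    se = float(np.sqrt(var))
    ci = (max(c_stat - _Z95 * se, 0.0), min(c_stat + _Z95 * se, 1.0))
    return DiscriminationResult(
        c_statistic=c_stat, ci=ci, se=se, comparable_pairs=int(round(m_pairs))
    )


def min_events_gate(n_events: int, threshold: int = 200) -> bool:
    """Whether a stratum has enough observed events for validation."""
    return n_events >= threshold
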