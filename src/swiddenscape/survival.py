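"""Recurrent-event survival analysis of fallow periods.

Each field contributes one at-risk interval per spell of forest cover: the
initial old-growth spell from the window start to the first cut, one fallow
spell per inter-cut interval (clock starting at the end of the cropping
phase, so durations are fallow ages), and a final right-censored spell after
the last cut.  Intervals are grouped into two calendar periods by the date at
which their at-risk clock starts, Kaplan-Meier curves are estimated per
period, and periods are compared with a log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

P1, P2 = "P1", "P2"


@dataclass
class SurvivalRecord:
    duration: float            # yr, > 0
    event: bool                # True = cut observed, False = right-censored
    period: str                # P1 | P2, by at-risk clock start date
    field_id: int
    kind: str = "fallow"       # "initial" (old-growth spell) | "fallow"


def build_survival_records(histories: list, window: tuple[float, float],
                           split_year: float, cropping_yr: float = 2.0
                           ) -> list[SurvivalRecord]:
    """Expand field histories into at-risk intervals with right censoring.

    An interval whose clock starts exactly at the split year belongs to the
    earlier period (P2 strictly after the split).
    """
    t0, t1 = window
    if not (t0 < split_year < t1):
        raise ValueError("split year must fall strictly inside the window")
    records: list[SurvivalRecord] = []

    def period_of(start: float) -> str:
        return P1 if start <= split_year else P2

    for h in histories:
        cuts = np.asarray(h.clearcut_dates, dtype=float)
        if len(cuts) > 1 and np.any(np.diff(cuts) <= 0):
            raise ValueError("clear-cut dates must be strictly ascending")
        if len(cuts) and (cuts[0] < t0 or cuts[-1] > t1):
            raise ValueError("window does not cover all break dates")
        fid = h.field_id
        if len(cuts) == 0:
            records.append(SurvivalRecord(t1 - t0, False, period_of(t0), fid, "initial"))
            continue
        if cuts[0] - t0 > 0:
            records.append(SurvivalRecord(float(cuts[0] - t0), True,
                                          period_of(t0), fid, "initial"))
        for a, b in zip(cuts[:-1], cuts[1:]):
            start = float(a + cropping_yr)
            records.append(SurvivalRecord(float(max(b - a - cropping_yr, 0.0)) or 1e-9,
                                          True, period_of(start), fid, "fallow"))
        tail = float((t1 - cuts[-1]) - cropping_yr)
        if tail > 0:
            records.append(SurvivalRecord(tail, False,
                                          period_of(float(cuts[-1] + cropping_yr)),
                                          fid, "fallow"))
    return records


@dataclass
class KMEstimate:
    times: np.ndarray          # event times where S steps
    survival: np.ndarray       # S(t) at those times
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    fitter: KaplanMeierFitter

    def sf(self, t: float | np.ndarray) -> np.ndarray | float:
        out = self.fitter.survival_function_at_times(np.atleast_1d(t)).to_numpy()
        return float(out[0]) if np.isscalar(t) else out


def km_estimate(records: list) -> KMEstimate:
    """Product-limit survival estimate with Greenwood confidence intervals."""
    if not records:
        raise ValueError("no survival records")
    dur = np.array([r.duration for r in records], dtype=float)
    evt = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(dur, event_observed=evt)
    tab = kmf.event_table
    sf = kmf.survival_function_.iloc[:, 0]
    ci = kmf.confidence_interval_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        at_risk=tab["at_risk"].to_numpy(),
        events=tab["observed"].to_numpy(),
        fitter=kmf,
    )


def logrank_test(records_a: list, records_b: list) -> dict:
    """Two-sample log-rank test (df = 1) that the two periods share one
    fallow-cutting hazard."""
    if not records_a or not records_b:
        raise ValueError("both groups must be nonempty")
    ea = np.array([r.event for r in records_a], dtype=bool)
    eb = np.array([r.event for r in records_b], dtype=bool)
    if ea.sum() == 0 and eb.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(
        np.array([r.duration for r in records_a]),
        np.array([r.duration for r in records_b]),
        event_observed_A=ea, event_observed_B=eb,
    )
    return {"chi2": float(res.test_statistic), "df": 1, "p_value": float(res.p_value)}


def fallow_age_summary(records: list, bin_width_yr: float = 1.0,
                       long_fallow_yr: float = 10.0) -> dict:
    """Summaries of completed fallow durations: mean, SD, a binned frequency
    distribution, and the share of fallows at least ``long_fallow_yr`` long.

    Only observed (event) fallow spells count — censored tails and the
    initial old-growth spell are not completed fallows.
    """
    dur = np.array([r.duration for r in records
                    if r.event and r.kind == "fallow"], dtype=float)
    if len(dur) == 0:
        raise ValueError("no completed fallow periods")
    edges = np.arange(0.0, np.ceil(dur.max() / bin_width_yr) * bin_width_yr
                      + bin_width_yr, bin_width_yr)
    counts, edges = np.histogram(dur, bins=edges)
    return {
        "n": int(len(dur)),
        "mean": float(dur.mean()),
        "sd": float(dur.std(ddof=1)) if len(dur) > 1 else 0.0,
        "hist_counts": counts,
        "hist_edges": edges,
        "frac_ge_long": float(np.mean(dur >= long_fallow_yr)),
    }
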