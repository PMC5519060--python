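"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation: exhaustive
enumeration instead of dynamic programming, textbook formulas instead of
library calls.
"""

from __future__ import annotations

import itertools

import numpy as np

RSS_FLOOR = 1e-12


def _ols_rss(t: np.ndarray, y: np.ndarray, t_origin: float, seasonal: bool) -> float:
    cols = [np.ones_like(t), t - t_origin]
    if seasonal:
        cols += [np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def exhaustive_piecewise(t: np.ndarray, y: np.ndarray, h_min: int,
                         max_breaks: int, seasonal: bool) -> tuple[float, tuple]:
    """Enumerate every admissible break placement; return (best BIC, splits)."""
    n = len(t)
    p = 4 if seasonal else 2
    logn = np.log(n)
    best = (np.inf, ())
    for k in range(0, max_breaks + 1):
        for splits in itertools.combinations(range(h_min, n - h_min + 1), k):
            bounds = (0,) + splits + (n,)
            if any(b - a < h_min for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            rss = sum(_ols_rss(t[a:b], y[a:b], t[0], seasonal)
                      for a, b in zip(bounds[:-1], bounds[1:]))
            bic = n * np.log(max(rss, RSS_FLOOR) / n) + ((k + 1) * p + k) * logn
            if bic < best[0] - 1e-12:
                best = (bic, splits)
    return best


def product_limit(durations, events) -> dict:
    """Hand Kaplan-Meier: S(t) after each distinct event time."""
    order = np.argsort(durations)
    d = np.asarray(durations, dtype=float)[order]
    e = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out = {}
    for td in np.unique(d[e]):
        at_risk = int(np.sum(d >= td))
        deaths = int(np.sum((d == td) & e))
        s *= 1.0 - deaths / at_risk
        out[float(td)] = s
    return out


def textbook_logrank(d1, e1, d2, e2) -> float:
    """Two-sample log-rank chi-square from the O-E aggregation over pooled
    event times (hypergeometric variance)."""
    d1, e1 = np.asarray(d1, float), np.asarray(e1, bool)
    d2, e2 = np.asarray(d2, float), np.asarray(e2, bool)
    times = np.unique(np.concatenate([d1[e1], d2[e2]]))
    o_minus_e = 0.0
    var = 0.0
    for td in times:
        n1 = np.sum(d1 >= td)
        n2 = np.sum(d2 >= td)
        o1 = np.sum((d1 == td) & e1)
        o2 = np.sum((d2 == td) & e2)
        n = n1 + n2
        o = o1 + o2
        if n < 2 or o == 0:
            continue
        e1_exp = o * n1 / n
        o_minus_e += o1 - e1_exp
        var += o * (n1 / n) * (n2 / n) * (n - o) / (n - 1)
    return float(o_minus_e ** 2 / var) if var > 0 else 0.0


def ols_closed_form(x, y) -> dict:
    """Normal-equation simple regression with slope t-test (textbook route)."""
    from scipy import stats as sps

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    rss = resid @ resid
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - rss / tss if tss > 0 else 1.0
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    se = np.sqrt(rss / (n - 2) / sxx)
    tval = slope / se if se > 0 else np.inf
    p = 2 * sps.t.sf(abs(tval), n - 2)
    return {"slope": slope, "adj_r2": adj, "p_value": p, "df": n - 2}
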