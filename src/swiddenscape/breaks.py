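"""Structural-break detection in irregular NDMI series.

Each segment's series is modelled as piecewise linear in time, optionally with
first-order annual harmonics (phenology of regrowing vegetation).  The number
and position of breakpoints are chosen jointly by minimizing

    BIC(k) = n * ln(RSS_k / n) + p_k * ln(n),      p_k = (k+1)*p_seg + k,

over k in [0, max_breaks], with breakpoints restricted to valid observation
indices and every temporal segment required to hold at least ``h_min`` valid
observations.  The optimization is exact: a dynamic program over candidate
split points, with per-segment ordinary least squares costs accumulated from
cumulative Gram matrices (O(n^2) candidate segments, each solved in O(p^3)).

Break time convention: a break is dated at the first observation of the
post-break temporal segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import AcquisitionSeries

_RSS_FLOOR = 1e-12  # keeps ln(RSS) finite on noise-free series; ties then fall to the penalty


def _design(t: np.ndarray, t_origin: float, seasonal: bool) -> np.ndarray:
    cols = [np.ones_like(t), t - t_origin]
    if seasonal:
        cols += [np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)]
    return np.column_stack(cols)


@dataclass
class SegmentFit:
    beta: np.ndarray          # coefficients on the design columns
    n_obs: int
    t_start: float
    t_end: float


@dataclass
class PiecewiseFit:
    break_times: np.ndarray          # ascending decimal years (possibly empty)
    break_indices: np.ndarray        # indices into the valid-observation arrays
    segments: list                   # list[SegmentFit], len = k + 1
    bic: float
    seasonal: bool
    t_origin: float
    undetectable: bool = False
    rss: float = np.nan

    @property
    def n_breaks(self) -> int:
        return len(self.break_times)

    def predict(self, t: np.ndarray | float, segment: int) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        X = _design(np.atleast_1d(t), self.t_origin, self.seasonal)
        out = X @ self.segments[segment].beta
        return float(out[0]) if t.ndim == 0 else out


@dataclass
class BreakRecord:
    """A detected structural break and its descriptive features."""

    time: float
    magnitude: float          # fitted value just after minus just before the break
    slope_before: float       # NDMI / yr
    slope_after: float
    duration_before: float    # length of the preceding temporal segment, yr
    label: str | None = None  # "clear-cut" | "stabilization", set by the classifier

    def features(self) -> np.ndarray:
        return np.array([self.magnitude, self.slope_before,
                         self.slope_after, self.duration_before])


def _segment_costs(t: np.ndarray, yc: np.ndarray, t_origin: float, h_min: int,
                   seasonal: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RSS of an OLS fit for every admissible contiguous observation block.

    ``yc`` must be mean-centered (the intercept absorbs the shift, and the
    centering keeps the y'y - b'beta cancellation on the residual scale).
    Returns (cost, S, Sy) where cost[i, j] is the RSS over obs[i:j] (inf where
    j - i < h_min) and S, Sy are the cumulative Gram terms reused for refits.
    """
    X = _design(t, t_origin, seasonal)
    n, p = X.shape
    S = np.concatenate([np.zeros((1, p, p)), np.cumsum(X[:, :, None] * X[:, None, :], axis=0)])
    Sy = np.concatenate([np.zeros((1, p)), np.cumsum(X * yc[:, None], axis=0)])
    Syy = np.concatenate([[0.0], np.cumsum(yc * yc)])
    cost = np.full((n + 1, n + 1), np.inf)
    ii = []
    jj = []
    for i in range(0, n - h_min + 1):
        js = np.arange(i + h_min, n + 1)
        ii.append(np.full(len(js), i))
        jj.append(js)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    G = S[jj] - S[ii]
    b = Sy[jj] - Sy[ii]
    yy = Syy[jj] - Syy[ii]
    beta = _batched_solve(G, b)
    rss = np.maximum(yy - np.einsum("mi,mi->m", b, beta), 0.0)
    cost[ii, jj] = rss
    return cost, S, Sy


def _batched_solve(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # rare singular block (e.g. duplicated times): tiny ridge fallback
        p = G.shape[-1]
        tr = np.einsum("...ii->...", G) / p
        Gr = G + (1e-9 * tr)[..., None, None] * np.eye(p)
        return np.linalg.solve(Gr, b[..., None])[..., 0]


def _solve_block(S: np.ndarray, Sy: np.ndarray, i: int, j: int) -> np.ndarray:
    G = S[j] - S[i]
    b = Sy[j] - Sy[i]
    return _batched_solve(G[None], b[None])[0]


def fit_piecewise(series: AcquisitionSeries, h_min: int = 12,
                  max_breaks: int = 8, seasonal: bool = True) -> PiecewiseFit:
    """Exact BIC-penalized piecewise OLS fit of one series.

    Series with fewer than ``2 * h_min`` valid observations are returned as an
    "undetectable" zero-break fit rather than raising: at Landsat cadence such
    series simply carry no break information.
    """
    p = 4 if seasonal else 2
    h_min = max(int(h_min), p + 1)
    t = series.valid_times()
    y = series.valid_values()
    n = len(t)
    if n < 2 * h_min:
        if n >= p + 1:
            X = _design(t, t[0], seasonal)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            seg = [SegmentFit(beta, n, t[0], t[-1])]
            rss = float(np.sum((y - X @ beta) ** 2))
        else:
            seg = [SegmentFit(np.zeros(p), n, t[0] if n else np.nan,
                              t[-1] if n else np.nan)]
            rss = np.nan
        return PiecewiseFit(np.empty(0), np.empty(0, dtype=int), seg, np.nan,
                            seasonal, t[0] if n else np.nan, undetectable=True, rss=rss)

    # center time and NDMI for conditioning; RSS is invariant to both shifts
    t_origin = float(t.mean())
    y_mean = float(y.mean())
    cost, S, Sy = _segment_costs(t, y - y_mean, t_origin, h_min, seasonal)
    k_max = min(max_breaks, n // h_min - 1)

    best = np.full((k_max + 1, n + 1), np.inf)
    arg = np.zeros((k_max + 1, n + 1), dtype=int)
    best[0] = cost[0]
    for k in range(1, k_max + 1):
        M = best[k - 1][:, None] + cost
        arg[k] = np.argmin(M, axis=0)
        best[k] = M[arg[k], np.arange(n + 1)]

    logn = np.log(n)
    bics = np.full(k_max + 1, np.inf)
    for k in range(k_max + 1):
        rss_k = best[k, n]
        if np.isfinite(rss_k):
            bics[k] = n * np.log(max(rss_k, _RSS_FLOOR) / n) + ((k + 1) * p + k) * logn
    k_star = int(np.argmin(bics))  # ties resolve to fewer breaks

    # backtrack split points
    splits = [n]
    j = n
    for k in range(k_star, 0, -1):
        j = int(arg[k, j])
        splits.append(j)
    splits.append(0)
    splits = splits[::-1]

    segments = []
    for a, b_ in zip(splits[:-1], splits[1:]):
        beta = _solve_block(S, Sy, a, b_)
        beta[0] += y_mean  # undo the response centering
        segments.append(SegmentFit(beta, b_ - a, t[a], t[b_ - 1]))
    bidx = np.asarray(splits[1:-1], dtype=int)
    return PiecewiseFit(t[bidx] if len(bidx) else np.empty(0), bidx, segments,
                        float(bics[k_star]), seasonal, t_origin,
                        rss=float(best[k_star, n]))


def detectable_window(series: AcquisitionSeries, h_min: int) -> tuple[float, float] | None:
    """Earliest and latest admissible break dates given the ``h_min`` margin
    at both ends of the valid record; None if no break is admissible at all."""
    if len(series) == 0:
        raise ValueError("series is empty")
    t = series.valid_times()
    n = len(t)
    if n < 2 * h_min:
        return None
    return float(t[h_min]), float(t[n - h_min])


def break_features(fit: PiecewiseFit, k: int) -> BreakRecord:
    """Features of break k: magnitude (right minus left fitted value at the
    break date, harmonics included), slopes, preceding-segment duration."""
    if not (0 <= k < fit.n_breaks):
        raise IndexError("break index out of range")
    tb = float(fit.break_times[k])
    left = fit.predict(tb, k)
    right = fit.predict(tb, k + 1)
    prev = float(fit.break_times[k - 1]) if k > 0 else fit.segments[0].t_start
    return BreakRecord(
        time=tb,
        magnitude=float(right - left),
        slope_before=float(fit.segments[k].beta[1]),
        slope_after=float(fit.segments[k + 1].beta[1]),
        duration_before=float(tb - prev),
    )


def all_break_records(fit: PiecewiseFit) -> list[BreakRecord]:
    return [break_features(fit, k) for k in range(fit.n_breaks)]
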