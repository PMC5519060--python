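"""Group neighbouring pixels with similar NDMI trajectories into fields.

Segmentation is deterministic single-pass region growing in row-major order:
a pixel joins the adjacent segment whose running mean trajectory is closest,
provided that distance does not exceed a threshold; otherwise it seeds a new
segment.  Distances are root-mean-square differences between series linearly
interpolated onto a common regular time grid, so irregular sampling and
per-pixel gaps do not bias the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import AcquisitionSeries, SeriesStack

HA_PER_PIXEL_30M = 0.09


def _grid(start: float, stop: float, step: float) -> np.ndarray:
    # anchored at t=0 so grids from different calls are commensurate
    k0 = np.ceil(start / step)
    k1 = np.floor(stop / step)
    return np.arange(k0, k1 + 1) * step


def trajectory_distance(a: AcquisitionSeries, b: AcquisitionSeries,
                        grid_step_yr: float = 0.25) -> float:
    """RMS difference of two series on a shared regular grid over their
    overlapping valid span."""
    for s in (a, b):
        if s.n_valid < 2:
            raise ValueError("need at least 2 valid observations per series")
    ta, va = a.valid_times(), a.valid_values()
    tb, vb = b.valid_times(), b.valid_values()
    lo = max(ta[0], tb[0])
    hi = min(ta[-1], tb[-1])
    if hi < lo:
        raise ValueError("series have no temporal overlap")
    g = _grid(lo, hi, grid_step_yr)
    if len(g) == 0:
        g = np.array([(lo + hi) / 2.0])
    ia = np.interp(g, ta, va)
    ib = np.interp(g, tb, vb)
    return float(np.sqrt(np.mean((ia - ib) ** 2)))


@dataclass
class SegmentMap:
    """Per-pixel segment ids (0 = excluded) with per-segment attributes."""

    labels: np.ndarray            # (H, W) int32, ids dense from 1
    n_pixels: np.ndarray          # (S,)
    area_ha: np.ndarray           # (S,)
    centroids: np.ndarray         # (S, 2) mean (row, col)

    @property
    def n_segments(self) -> int:
        return len(self.n_pixels)

    def pixels_of(self, seg_id: int) -> np.ndarray:
        rr, cc = np.nonzero(self.labels == seg_id)
        return np.column_stack([rr, cc])


def _gridded(stack: SeriesStack, grid_step_yr: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate every pixel's valid observations onto the global grid.

    Returns (G, H, W) values with NaN outside a pixel's valid span or for
    pixels with < 2 valid observations, and the grid itself.
    """
    t = stack.times
    g = _grid(t[0], t[-1], grid_step_yr)
    T, h, w = stack.values.shape
    out = np.full((len(g), h, w), np.nan)
    for r in range(h):
        for c in range(w):
            m = stack.valid[:, r, c]
            if m.sum() < 2:
                continue
            tv = t[m]
            span = (g >= tv[0]) & (g <= tv[-1])
            out[span, r, c] = np.interp(g[span], tv, stack.values[m, r, c])
    return out, g


def segment_landscape(stack: SeriesStack, include_mask: np.ndarray,
                      threshold_tau: float = 0.1, connectivity: int = 4,
                      grid_step_yr: float = 0.25) -> SegmentMap:
    """Region-growing segmentation of the included pixels.

    Scan order is row-major; a pixel is compared against the running mean
    trajectory of each already-labelled neighbouring segment and joins the
    closest one within ``threshold_tau``, else starts a new segment.
    Under-merging is preferred to merging fields with different histories.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    h, w = stack.shape
    include_mask = np.asarray(include_mask, dtype=bool)
    labels = np.zeros((h, w), dtype=np.int32)
    if not include_mask.any():
        return SegmentMap(labels, np.zeros(0, dtype=int), np.zeros(0), np.zeros((0, 2)))

    gv, _ = _gridded(stack, grid_step_yr)
    G = gv.shape[0]
    # running per-segment sums over grid points (NaN-aware)
    seg_sum: list[np.ndarray] = []
    seg_cnt: list[np.ndarray] = []

    if connectivity == 4:
        offsets = ((-1, 0), (0, -1))
    else:
        offsets = ((-1, -1), (-1, 0), (-1, 1), (0, -1))

    px_per_ha = (stack.transform[2] ** 2) / 1e4
    for r in range(h):
        for c in range(w):
            if not include_mask[r, c]:
                continue
            v = gv[:, r, c]
            vok = ~np.isnan(v)
            best_id, best_d = 0, np.inf
            if vok.any():
                seen = set()
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                        sid = labels[rr, cc]
                        if sid in seen:
                            continue
                        seen.add(sid)
                        cnt = seg_cnt[sid - 1]
                        both = vok & (cnt > 0)
                        if not both.any():
                            continue
                        mean = seg_sum[sid - 1][both] / cnt[both]
                        d = float(np.sqrt(np.mean((v[both] - mean) ** 2)))
                        if d < best_d:
                            best_id, best_d = sid, d
            if best_id and best_d <= threshold_tau:
                sid = best_id
            else:
                seg_sum.append(np.zeros(G))
                seg_cnt.append(np.zeros(G, dtype=np.int64))
                sid = len(seg_sum)
            labels[r, c] = sid
            if vok.any():
                seg_sum[sid - 1][vok] += v[vok]
                seg_cnt[sid - 1][vok] += 1

    n_seg = len(seg_sum)
    n_pixels = np.zeros(n_seg, dtype=int)
    centroids = np.zeros((n_seg, 2))
    rr, cc = np.nonzero(labels)
    for r, c in zip(rr, cc):
        sid = labels[r, c] - 1
        n_pixels[sid] += 1
        centroids[sid, 0] += r
        centroids[sid, 1] += c
    centroids /= np.maximum(n_pixels, 1)[:, None]
    return SegmentMap(labels, n_pixels, n_pixels * px_per_ha, centroids)


def segment_mean_series(pixels: np.ndarray, stack: SeriesStack) -> AcquisitionSeries:
    """Per-date mean over a segment's valid pixel observations; a date is
    valid iff at least one member pixel is valid there."""
    if len(pixels) == 0:
        raise ValueError("segment is empty")
    vals = stack.values[:, pixels[:, 0], pixels[:, 1]]
    ok = stack.valid[:, pixels[:, 0], pixels[:, 1]]
    cnt = ok.sum(axis=1)
    s = np.where(ok, vals, 0.0).sum(axis=1)
    mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return AcquisitionSeries(stack.times, np.where(cnt > 0, mean, 0.0), cnt > 0)
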