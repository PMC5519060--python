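"""Field sampling and covariates for the landscape-scale statistical models.

One random sample point per field, points at least 70 m apart (so adjacent
30 m pixels of one field are never double-sampled), Euclidean distance to the
nearest community's housing centre, and household-count village-size classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedlm import LMMFit, fit_lmm, select_model  # noqa: F401  (re-exported surface)
from .segmentation import SegmentMap

VILLAGE_BINS = (
    ("isolated", 1, 3),
    ("small", 4, 10),
    ("medium", 11, 29),
    ("large", 30, None),
)


def village_size_class(households: int) -> str:
    """Household-count bins: 1-3 isolated, 4-10 small, 11-29 medium, >=30 large."""
    if households < 1:
        raise ValueError("a community has at least 1 household")
    for name, lo, hi in VILLAGE_BINS:
        if households >= lo and (hi is None or households <= hi):
            return name
    raise AssertionError("unreachable")


def distance_to_residences(centroid_km: tuple[float, float],
                           communities_km: np.ndarray) -> float:
    """Euclidean distance (km) to the nearest community centre."""
    communities_km = np.atleast_2d(np.asarray(communities_km, dtype=float))
    if communities_km.size == 0:
        raise ValueError("no communities supplied")
    d = np.hypot(communities_km[:, 0] - centroid_km[0],
                 communities_km[:, 1] - centroid_km[1])
    return float(d.min())


@dataclass
class SampledField:
    field_id: int
    point_xy_m: tuple[float, float]
    current_age: float = np.nan
    n_cycles: int = 0
    distance_km: float = np.nan
    village_class: str = ""
    community_id: int = -1


def sample_fields(segment_map: SegmentMap, rng: np.random.Generator,
                  n_points: int = 5000, min_spacing_m: float = 70.0,
                  pixel_size_m: float = 30.0) -> list[SampledField]:
    """Random point sampling of the segmented landscape.

    Candidate points are uniform over the map extent; a point is kept if it
    falls inside a segment, lies at least ``min_spacing_m`` from every kept
    point, and its segment has not been sampled yet.  May return fewer points
    than requested.
    """
    labels = segment_map.labels
    if segment_map.n_segments == 0:
        raise ValueError("segment map is empty")
    h, w = labels.shape
    kept_xy: list[tuple[float, float]] = []
    kept: list[SampledField] = []
    seen: set[int] = set()
    xs = rng.uniform(0, w * pixel_size_m, size=n_points)
    ys = rng.uniform(0, h * pixel_size_m, size=n_points)
    cell = min_spacing_m  # spatial hash for the spacing check
    buckets: dict[tuple[int, int], list[int]] = {}
    for x, y in zip(xs, ys):
        r, c = int(y // pixel_size_m), int(x // pixel_size_m)
        sid = int(labels[r, c])
        if sid == 0 or sid in seen:
            continue
        bx, by = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for k in buckets.get((bx + dx, by + dy), ()):
                    px, py = kept_xy[k]
                    if (px - x) ** 2 + (py - y) ** 2 < min_spacing_m ** 2:
                        ok = False
                        break
        if not ok:
            continue
        seen.add(sid)
        buckets.setdefault((bx, by), []).append(len(kept_xy))
        kept_xy.append((x, y))
        kept.append(SampledField(sid, (float(x), float(y))))
    return kept


def sampled_table(samples: list[SampledField]) -> pd.DataFrame:
    """Analysis table with the village class ordered so 'isolated' is the
    reference category of the mixed models."""
    df = pd.DataFrame({
        "field_id": [s.field_id for s in samples],
        "current_age": [s.current_age for s in samples],
        "n_cycles": [s.n_cycles for s in samples],
        "distance_km": [s.distance_km for s in samples],
        "village_class": [s.village_class for s in samples],
        "community": [s.community_id for s in samples],
    })
    df["village_class"] = pd.Categorical(
        df["village_class"], categories=["isolated", "small", "medium", "large"],
        ordered=True)
    return df
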