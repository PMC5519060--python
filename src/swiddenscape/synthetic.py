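"""Synthetic riverine shifting-cultivation landscapes with known ground truth.

Emulates three decades of Landsat-like monitoring of a swidden-fallow mosaic:
a grid of 30 m pixels grouped into fields, each field cycling between cropping
(after an abrupt clear-cut) and secondary-forest fallow (saturating NDMI
recovery), observed on an irregular, gappy acquisition calendar.  Fallow
lengths depend on distance to the nearest community, on village size, and on
the calendar period, so the downstream statistics have a known sign structure
to recover.

Every stochastic element draws from an explicit generator; identical
(config, seed) pairs produce bit-identical truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from .raster import AcquisitionSeries, SeriesStack

# Six-class cover legend of the reference scene.
OLD_GROWTH, AGRICULTURAL, BARE_SOIL, CLOUD, SHADOW, WATER = 1, 2, 3, 4, 5, 6
COVER_CLASSES = {
    OLD_GROWTH: "old-growth forest",
    AGRICULTURAL: "agricultural field",
    BARE_SOIL: "bare soil",
    CLOUD: "cloud",
    SHADOW: "shadow",
    WATER: "water",
}

VILLAGE_CLASSES = ("isolated", "small", "medium", "large")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic landscape.

    Defaults describe the standard monitoring scenario: 16-day acquisitions
    over 1984.5-2015.6 with 50 % missingness, NDMI dropping from an old-growth
    level of 0.45 to 0.05 at a clear-cut and recovering with a 4-yr timescale,
    annual seasonality of amplitude 0.03 and observation noise of 0.04.
    Fallow lengths are lognormal with a log-mean linear in distance to
    residences (km), village-size class, and a calendar-period indicator.
    """

    n_communities: int = 31
    households_range: tuple[int, int] = (1, 45)
    n_fields: int = 300
    pixels_per_field: tuple[int, int] = (4, 12)
    pixel_size_m: float = 30.0
    acquisition_interval_days: float = 16.0
    time_span: tuple[float, float] = (1984.5, 2015.6)
    missingness_prob: float = 0.5
    ndmi_oldgrowth_mean: float = 0.45
    ndmi_postcut_mean: float = 0.05
    regrowth_timescale_yr: float = 4.0
    season_amplitude: float = 0.03
    noise_sd: float = 0.04
    cropping_period_yr: float = 2.0
    # fallow-length model (log scale): log mean = log(mean_fallow_yr)
    #   + distance_effect * distance_km + village_effect[class]
    #   + period_effect * 1[interval starts after period_split_year]
    mean_fallow_yr: float = 5.2
    fallow_log_sd: float = 0.40
    distance_effect: float = 0.10
    village_effects: dict = dc_field(default_factory=lambda: {
        "isolated": 0.0, "small": -0.08, "medium": -0.15, "large": -0.25})
    period_split_year: float = 2001.0
    period_effect: float = -0.22
    first_cut_factor: float = 2.2
    prob_agricultural_1984: float = 0.25
    census_year: float = 2014.6
    # reference-scene rendering
    scene_n_bands: int = 6
    scene_noise_sd: float = 0.02
    scene_class_separation: float = 6.0  # class-mean offset in units of scene_noise_sd
    bare_soil_yr: float = 0.75       # a just-cut field shows bare soil this long
    cloud_frac: float = 0.03
    shadow_frac: float = 0.02
    water_frac: float = 0.05
    grid_shape: tuple[int, int] | None = None
    # geographic frame the field mosaic is embedded in (study-region scale);
    # distances to communities live here, pixel areas on the 30 m grid
    landscape_extent_km: tuple[float, float] = (12.0, 9.0)
    seed: int = 42

    def validate(self) -> None:
        if not (0.0 <= self.missingness_prob <= 1.0):
            raise ValueError("missingness_prob must be in [0, 1]")
        if self.time_span[0] >= self.time_span[1]:
            raise ValueError("time_span start must precede end")
        for name in ("regrowth_timescale_yr", "cropping_period_yr",
                     "acquisition_interval_days", "pixel_size_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ndmi_oldgrowth_mean", "ndmi_postcut_mean"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.n_fields < 1 or self.n_communities < 1:
            raise ValueError("need at least one field and one community")
        if self.pixels_per_field[0] < 1 or self.pixels_per_field[0] > self.pixels_per_field[1]:
            raise ValueError("invalid pixels_per_field range")


@dataclass
class Community:
    id: int
    location_km: tuple[float, float]
    households: int
    village_class: str


@dataclass
class Field:
    id: int
    pixels: np.ndarray                 # (n, 2) row/col indices, spatially connected
    centroid_rc: tuple[float, float]
    centroid_km: tuple[float, float]
    community_id: int
    distance_km: float
    village_class: str
    prior_cut: float | None            # last clear-cut before the monitored span, if any
    clearcut_dates: np.ndarray         # ascending decimal years within the span
    cover_1984: int
    area_ha: float

    def all_cut_dates(self) -> np.ndarray:
        """Cut dates including any pre-span cut (drives the NDMI start state)."""
        if self.prior_cut is None:
            return self.clearcut_dates
        return np.concatenate([[self.prior_cut], self.clearcut_dates])


@dataclass
class LandscapeTruth:
    communities: list
    fields: list
    acquisition_dates: np.ndarray
    grid_shape: tuple[int, int]
    config: GeneratorConfig

    def field_label_map(self) -> np.ndarray:
        """(H, W) int array: field id per pixel, 0 for background."""
        lab = np.zeros(self.grid_shape, dtype=np.int32)
        for f in self.fields:
            lab[f.pixels[:, 0], f.pixels[:, 1]] = f.id
        return lab

    def final_cover(self) -> np.ndarray:
        """Per-pixel cover class at the end of the span (old-growth vs agricultural)."""
        cover = np.full(self.grid_shape, OLD_GROWTH, dtype=np.uint8)
        for f in self.fields:
            if len(f.all_cut_dates()):
                cover[f.pixels[:, 0], f.pixels[:, 1]] = AGRICULTURAL
        return cover

    def mean_ndmi_fn(self, field_id: int) -> Callable[[np.ndarray], np.ndarray]:
        f = self.fields[field_id - 1]
        cfg = self.config
        cuts = f.all_cut_dates()
        return lambda t: _mean_ndmi(np.asarray(t, dtype=float), cuts, cfg)


def _mean_ndmi(times: np.ndarray, cuts: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Noise-free, season-free NDMI path: old-growth level before the first cut,
    an instantaneous drop at each cut, exponential-saturating recovery after."""
    hi, lo, tau = cfg.ndmi_oldgrowth_mean, cfg.ndmi_postcut_mean, cfg.regrowth_timescale_yr
    out = np.full(times.shape, hi, dtype=float)
    if len(cuts) == 0:
        return out
    idx = np.searchsorted(cuts, times, side="right")  # number of cuts at or before t
    has_cut = idx > 0
    last = cuts[np.maximum(idx - 1, 0)]
    dt = times - last
    rec = lo + (hi - lo) * (1.0 - np.exp(-dt / tau))
    out[has_cut] = rec[has_cut]
    return out


def acquisition_calendar(cfg: GeneratorConfig) -> np.ndarray:
    """Fixed-interval acquisition grid in decimal years (thinned later per pixel)."""
    step = cfg.acquisition_interval_days / 365.25
    return np.arange(cfg.time_span[0], cfg.time_span[1], step)


def _fallow_log_mean(distance_km: float, village_class: str, t: float,
                     cfg: GeneratorConfig) -> float:
    mu = (math.log(cfg.mean_fallow_yr)
          + cfg.distance_effect * distance_km
          + cfg.village_effects[village_class])
    if t > cfg.period_split_year:
        mu += cfg.period_effect
    # lognormal(mu_adj, s) has mean exp(mu): shift so configured means are means
    return mu - 0.5 * cfg.fallow_log_sd ** 2


def simulate_event_history(distance_km: float, village_class: str,
                           config: GeneratorConfig, rng: np.random.Generator,
                           prior_cut: float | None = None) -> list[float]:
    """Renewal process of clear-cut dates within the monitored span.

    Gaps between cuts are (cropping period + lognormal fallow draw); the
    fallow log-mean is linear in distance, village-size class, and a period
    indicator evaluated at the interval start.  A field whose first waiting
    time exceeds the span is never cut (old-growth remains).
    """
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    t0, t1 = config.time_span
    s = config.fallow_log_sd
    if not math.isfinite(config.mean_fallow_yr):
        return []
    dates: list[float] = []
    if prior_cut is None:
        mu = _fallow_log_mean(distance_km, village_class, t0, config)
        wait = rng.lognormal(mu + math.log(config.first_cut_factor), s)
        t = t0 + wait
    else:
        t = prior_cut
        while True:
            mu = _fallow_log_mean(distance_km, village_class, t, config)
            t = t + config.cropping_period_yr + rng.lognormal(mu, s)
            if t >= t0:
                break
    while t < t1:
        dates.append(float(t))
        mu = _fallow_log_mean(distance_km, village_class, t, config)
        t = t + config.cropping_period_yr + rng.lognormal(mu, s)
    return dates


def simulate_ndmi_trajectory(clearcut_dates, acquisition_dates,
                             config: GeneratorConfig,
                             rng: np.random.Generator) -> AcquisitionSeries:
    """One pixel's observed NDMI series for a given clear-cut chronology.

    Mean path from :func:`_mean_ndmi`, plus sinusoidal annual seasonality and
    i.i.d. Gaussian noise; observations are dropped independently with the
    configured missingness probability; retained values are clipped to [-1, 1].
    """
    cuts = np.asarray(clearcut_dates, dtype=float)
    t = np.asarray(acquisition_dates, dtype=float)
    if len(cuts) > 1:
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("clear-cut dates must be strictly ascending")
        if np.any(np.diff(cuts) <= config.cropping_period_yr):
            raise ValueError("clear-cuts overlap: gap within the cropping period")
    mean = _mean_ndmi(t, cuts, config)
    values = (mean
              + config.season_amplitude * np.sin(2 * np.pi * t)
              + rng.normal(0.0, config.noise_sd, size=t.shape))
    values = np.clip(values, -1.0, 1.0)
    valid = rng.random(t.shape) >= config.missingness_prob
    return AcquisitionSeries(t, values, valid)


def _field_shape(n_pixels: int, origin: tuple[int, int]) -> np.ndarray:
    """Connected pixel block: rows of width ceil(sqrt(n)), filled row-major."""
    w = int(math.ceil(math.sqrt(n_pixels)))
    r0, c0 = origin
    px = [(r0 + k // w, c0 + k % w) for k in range(n_pixels)]
    return np.asarray(px, dtype=np.int64)


def generate_landscape(config: GeneratorConfig) -> LandscapeTruth:
    """Lay out fields and communities, then simulate each field's cut history.

    Fields are placed in disjoint slots on the pixel grid (so pixel sets are
    disjoint and connected); each field is assigned to its nearest community,
    whose household count determines the village-size class.  Household draws
    always cover all four size classes.
    """
    from .stats import village_size_class

    config.validate()
    rng = np.random.default_rng(config.seed)
    max_px = config.pixels_per_field[1]
    slot = int(math.ceil(math.sqrt(max_px))) + 1
    n_cols = int(math.ceil(math.sqrt(config.n_fields)))
    n_rows = int(math.ceil(config.n_fields / n_cols))
    if config.grid_shape is not None:
        h, w = config.grid_shape
        if (h // slot) * (w // slot) < config.n_fields:
            raise ValueError(
                f"grid {config.grid_shape} cannot hold {config.n_fields} fields "
                f"of slot size {slot}")
        n_rows, n_cols = h // slot, w // slot
        grid_shape = (h, w)
    else:
        grid_shape = (n_rows * slot, n_cols * slot)

    extent_km = config.landscape_extent_km

    # communities: the first four households draws pin one community per class
    pinned = [2, 7, 20, 40]
    communities = []
    for i in range(config.n_communities):
        loc = (rng.uniform(0, extent_km[0]), rng.uniform(0, extent_km[1]))
        hh = pinned[i] if i < len(pinned) and config.n_communities >= 4 else int(
            rng.integers(config.households_range[0], config.households_range[1] + 1))
        communities.append(Community(i + 1, loc, hh, village_size_class(hh)))
    comm_xy = np.asarray([c.location_km for c in communities])

    # choose field slots in a fixed (shuffled) order for reproducibility
    slots = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    order = rng.permutation(len(slots))[:config.n_fields]

    fields = []
    for fid, si in enumerate(order, start=1):
        sr, sc = slots[si]
        n_px = int(rng.integers(config.pixels_per_field[0], config.pixels_per_field[1] + 1))
        px = _field_shape(n_px, (sr * slot, sc * slot))
        cen_rc = (float(px[:, 0].mean()), float(px[:, 1].mean()))
        # x from column, y from row, mapped onto the geographic frame
        cen_km = ((cen_rc[1] + 0.5) / grid_shape[1] * extent_km[0],
                  (cen_rc[0] + 0.5) / grid_shape[0] * extent_km[1])
        d = np.hypot(comm_xy[:, 0] - cen_km[0], comm_xy[:, 1] - cen_km[1])
        ci = int(np.argmin(d))
        comm = communities[ci]
        prior = None
        if rng.random() < config.prob_agricultural_1984:
            prior = float(config.time_span[0] - rng.uniform(0.05, 10.0))
        cuts = simulate_event_history(float(d[ci]), comm.village_class, config,
                                      rng, prior_cut=prior)
        cover = AGRICULTURAL if prior is not None else OLD_GROWTH
        area = n_px * (config.pixel_size_m ** 2) / 1e4
        fields.append(Field(fid, px, cen_rc, cen_km, comm.id, float(d[ci]),
                            comm.village_class, prior,
                            np.asarray(cuts, dtype=float), cover, area))

    return LandscapeTruth(communities, fields, acquisition_calendar(config),
                          grid_shape, config)


def simulate_stack(truth: LandscapeTruth, rng: np.random.Generator) -> SeriesStack:
    """Observed NDMI stack for a whole landscape (shared calendar, per-pixel
    noise and missingness).  Background pixels follow the old-growth mean."""
    cfg = truth.config
    t = truth.acquisition_dates
    h, w = truth.grid_shape
    season = cfg.season_amplitude * np.sin(2 * np.pi * t)
    mean = np.empty((len(t), h, w), dtype=float)
    mean[:] = (cfg.ndmi_oldgrowth_mean + season)[:, None, None]
    for f in truth.fields:
        path = _mean_ndmi(t, f.all_cut_dates(), cfg) + season
        mean[:, f.pixels[:, 0], f.pixels[:, 1]] = path[:, None]
    values = np.clip(mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape), -1.0, 1.0)
    valid = rng.random(mean.shape) >= cfg.missingness_prob
    return SeriesStack(t, values, valid, (0.0, 0.0, cfg.pixel_size_m))


def render_reference_scene(truth: LandscapeTruth, date: float,
                           config: GeneratorConfig, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-band reference image plus true per-pixel six-class cover labels.

    Land labels follow the cut chronology (bare soil shortly after a cut,
    agricultural field for any previously cut pixel — fallows included — and
    old-growth otherwise); cloud, shadow and water patches are overlaid at the
    configured fractions.  Bands are Gaussian around class-conditional means
    separated by ``scene_class_separation`` noise standard deviations.
    """
    if not (config.time_span[0] - 15.0 <= date <= config.time_span[1]):
        raise ValueError("reference date outside the simulated span")
    h, w = truth.grid_shape
    labels = np.full((h, w), OLD_GROWTH, dtype=np.uint8)
    for f in truth.fields:
        cuts = f.all_cut_dates()
        past = cuts[cuts <= date]
        if len(past) == 0:
            continue
        cls = BARE_SOIL if (date - past[-1]) <= config.bare_soil_yr else AGRICULTURAL
        labels[f.pixels[:, 0], f.pixels[:, 1]] = cls
    u = rng.random((h, w))
    labels[u < config.water_frac] = WATER
    labels[(u >= config.water_frac) & (u < config.water_frac + config.cloud_frac)] = CLOUD
    hi = config.water_frac + config.cloud_frac + config.shadow_frac
    labels[(u >= config.water_frac + config.cloud_frac) & (u < hi)] = SHADOW

    nb = config.scene_n_bands
    sd = config.scene_noise_sd
    means = np.full((7, nb), 0.2)  # index by class code 1..6
    for k in range(1, 7):
        means[k, (k - 1) % nb] += config.scene_class_separation * sd
    bands = means[labels] + rng.normal(0.0, sd, size=(h, w, nb))
    return np.clip(bands, 0.0, None), labels
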