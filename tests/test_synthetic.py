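import numpy as np
import pytest

from swiddenscape.synthetic import (AGRICULTURAL, BARE_SOIL, CLOUD, OLD_GROWTH,
                                    SHADOW, WATER, GeneratorConfig,
                                    _fallow_log_mean, acquisition_calendar,
                                    generate_landscape, render_reference_scene,
                                    simulate_event_history,
                                    simulate_ndmi_trajectory)
from tests.conftest import small_config


def _connected(pixels: np.ndarray) -> bool:
    px = {tuple(p) for p in pixels}
    seen = {next(iter(px))}
    frontier = list(seen)
    while frontier:
        r, c = frontier.pop()
        for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if nb in px and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return seen == px


def test_single_field_count_and_connectivity():
    cfg = small_config(n_fields=1, pixels_per_field=(4, 4))
    truth = generate_landscape(cfg)
    assert len(truth.fields) == 1
    assert len(truth.fields[0].pixels) == 4
    assert _connected(truth.fields[0].pixels)


def test_determinism_same_seed_identical_truth():
    a = generate_landscape(small_config(seed=11))
    b = generate_landscape(small_config(seed=11))
    assert np.array_equal(a.acquisition_dates, b.acquisition_dates)
    for fa, fb in zip(a.fields, b.fields):
        assert np.array_equal(fa.pixels, fb.pixels)
        assert np.array_equal(fa.clearcut_dates, fb.clearcut_dates)
        assert fa.distance_km == fb.distance_km


def test_all_four_village_classes_present(small_truth):
    classes = {c.village_class for c in small_truth.communities}
    assert classes == {"isolated", "small", "medium", "large"}


def test_pixel_sets_disjoint_and_area_conserved(small_truth):
    seen = set()
    total_px = 0
    for f in small_truth.fields:
        for p in map(tuple, f.pixels):
            assert p not in seen
            seen.add(p)
        total_px += len(f.pixels)
        assert _connected(f.pixels)
    area = sum(f.area_ha for f in small_truth.fields)
    assert area == pytest.approx(total_px * 0.09)


def test_infeasible_geometry_raises():
    with pytest.raises(ValueError, match="cannot hold"):
        generate_landscape(small_config(n_fields=50, grid_shape=(8, 8)))


def test_event_history_infinite_fallow_never_cut(rng):
    cfg = small_config(mean_fallow_yr=np.inf)
    assert simulate_event_history(1.0, "small", cfg, rng) == []


def test_event_history_gap_invariant(rng):
    cfg = GeneratorConfig(mean_fallow_yr=5.0)
    for _ in range(20):
        dates = simulate_event_history(1.0, "small", cfg, rng)
        if len(dates) > 1:
            assert np.all(np.diff(dates) > cfg.cropping_period_yr)
        t0, t1 = cfg.time_span
        assert all(t0 < d < t1 for d in dates)


def test_fallow_mean_increases_with_distance(rng):
    cfg = GeneratorConfig()
    s = cfg.fallow_log_sd
    near = rng.lognormal(_fallow_log_mean(1.0, "small", 1990.0, cfg), s, 10_000)
    far = rng.lognormal(_fallow_log_mean(4.0, "small", 1990.0, cfg), s, 10_000)
    assert far.mean() > near.mean()


def test_fallow_mean_matches_configured_mean(rng):
    # generator consistency: sample mean converges to the configured mean
    cfg = GeneratorConfig()
    draws = rng.lognormal(_fallow_log_mean(0.0, "isolated", 1990.0, cfg),
                          cfg.fallow_log_sd, 10_000)
    se = draws.std(ddof=1) / 100.0
    assert abs(draws.mean() - cfg.mean_fallow_yr) < 2 * se


def test_trajectory_constant_without_cuts_noise_or_season(rng):
    cfg = small_config(noise_sd=0.0, season_amplitude=0.0, missingness_prob=0.0)
    t = acquisition_calendar(cfg)
    s = simulate_ndmi_trajectory([], t, cfg, rng)
    assert np.allclose(s.values, cfg.ndmi_oldgrowth_mean)
    assert s.valid.all()


def test_trajectory_recovery_arithmetic(rng):
    cfg = small_config(noise_sd=0.0, season_amplitude=0.0, missingness_prob=0.0)
    cut = 1995.0
    t = np.array([cut + 1e-6, cut + 5 * cfg.regrowth_timescale_yr])
    s = simulate_ndmi_trajectory([cut], t, cfg, rng)
    assert s.values[0] == pytest.approx(cfg.ndmi_postcut_mean, abs=1e-4)
    assert s.values[1] == pytest.approx(cfg.ndmi_oldgrowth_mean,
                                        rel=0.01)


def test_trajectory_rejects_overlapping_cuts(rng):
    cfg = small_config()
    with pytest.raises(ValueError, match="overlap"):
        simulate_ndmi_trajectory([2000.0, 2001.5], acquisition_calendar(cfg), cfg, rng)


def test_missingness_binomial(rng):
    # 380 dates at 50% retention, 1000 replicates: mean retained count must sit
    # within the 99% bounds of the binomial mean
    cfg = small_config(missingness_prob=0.5)
    t = np.linspace(1990, 2005, 380)
    counts = [simulate_ndmi_trajectory([], t, cfg, rng).n_valid for _ in range(1000)]
    se_mean = np.sqrt(380 * 0.25 / 1000)
    assert abs(np.mean(counts) - 190.0) < 2.576 * se_mean


def test_reference_scene_labels(rng):
    cfg = small_config(cloud_frac=0.0, shadow_frac=0.0, water_frac=0.0,
                       prob_agricultural_1984=0.0)
    truth = generate_landscape(cfg)
    # before any cut: everything old-growth
    bands, labels = render_reference_scene(truth, cfg.time_span[0] + 0.01, cfg,
                                           np.random.default_rng(0))
    cut_dates = np.concatenate([f.clearcut_dates for f in truth.fields])
    assert (labels == OLD_GROWTH).all() or cut_dates.min() < cfg.time_span[0] + 0.01
    # a field cut one year before the reference date is an agricultural field
    f = next(f for f in truth.fields if len(f.clearcut_dates))
    date = float(f.clearcut_dates[0]) + 1.0
    _, labels2 = render_reference_scene(truth, date, cfg, np.random.default_rng(0))
    assert (labels2[f.pixels[:, 0], f.pixels[:, 1]] == AGRICULTURAL).all()


def test_reference_scene_nearest_mean_error(rng):
    # default class separation: nearest-mean labelling error < 0.1% over 10^4 px
    cfg = GeneratorConfig(n_fields=100, grid_shape=(100, 100), seed=5)
    truth = generate_landscape(cfg)
    bands, labels = render_reference_scene(truth, 2000.0, cfg, rng)
    means = np.full((7, cfg.scene_n_bands), 0.2)
    for k in range(1, 7):
        means[k, (k - 1) % cfg.scene_n_bands] += cfg.scene_class_separation * cfg.scene_noise_sd
    d2 = ((bands[:, :, None, :] - means[None, None, 1:, :]) ** 2).sum(axis=-1)
    pred = np.argmin(d2, axis=-1) + 1
    assert np.mean(pred != labels) < 1e-3
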