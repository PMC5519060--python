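import numpy as np
import pytest

from swiddenscape.raster import AcquisitionSeries, SeriesStack
from swiddenscape.segmentation import (segment_landscape, segment_mean_series,
                                       trajectory_distance)


def _series(times, values, valid=None):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(times), dtype=bool)
    return AcquisitionSeries(times, values, valid)


def test_distance_identity_and_offset():
    t = np.linspace(2000, 2010, 40)
    a = _series(t, 0.3 + 0.01 * np.sin(t))
    assert trajectory_distance(a, a) == 0.0
    b = _series(t, a.values + 0.2)
    assert trajectory_distance(a, b) == pytest.approx(0.2, abs=1e-12)


def test_distance_matches_brute_force_oracle(rng):
    # independent re-computation: explicit loop over anchored grid points
    for _ in range(20):
        ta = np.sort(rng.uniform(1995, 2010, 30))
        tb = np.sort(rng.uniform(1996, 2012, 25))
        a = _series(ta, rng.uniform(-0.5, 0.5, 30))
        b = _series(tb, rng.uniform(-0.5, 0.5, 25))
        step = 0.25
        lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
        gs = [k * step for k in range(int(np.ceil(lo / step)),
                                      int(np.floor(hi / step)) + 1)]
        if not gs:
            gs = [(lo + hi) / 2]
        sq = [(np.interp(g, ta, a.values) - np.interp(g, tb, b.values)) ** 2
              for g in gs]
        expected = float(np.sqrt(np.mean(sq)))
        assert trajectory_distance(a, b, step) == pytest.approx(expected, abs=1e-10)


def test_distance_errors():
    a = _series([2000.0, 2001.0], [0.1, 0.2])
    b = _series([2005.0, 2006.0], [0.1, 0.2])
    with pytest.raises(ValueError, match="overlap"):
        trajectory_distance(a, b)
    c = _series([2000.0, 2001.0], [0.1, 0.2], [True, False])
    with pytest.raises(ValueError, match="valid"):
        trajectory_distance(a, c)


def _stack_from_histories(histories, h, w, assign, times=None):
    """Noise-free stack: assign[(r,c)] -> index into histories (step functions)."""
    if times is None:
        times = np.linspace(1990.0, 2010.0, 80)
    values = np.zeros((len(times), h, w))
    for (r, c), hi in assign.items():
        cut = histories[hi]
        values[:, r, c] = np.where(times < cut, 0.5, 0.1) if cut else 0.5
    return SeriesStack(times, values, np.ones_like(values, dtype=bool))


def test_identical_adjacent_fields_merge():
    stack = _stack_from_histories([2000.0], 1, 4,
                                  {(0, i): 0 for i in range(4)})
    seg = segment_landscape(stack, np.ones((1, 4), bool), threshold_tau=0.05)
    assert seg.n_segments == 1
    assert (seg.labels == 1).all()


def test_distinct_histories_recover_truth_boundaries():
    from sklearn.metrics import adjusted_rand_score

    h, w = 4, 6
    assign = {(r, c): (0 if c < 3 else 1) for r in range(h) for c in range(w)}
    stack = _stack_from_histories([1995.0, 2005.0], h, w, assign)
    seg = segment_landscape(stack, np.ones((h, w), bool), threshold_tau=0.05)
    truth = np.array([[assign[(r, c)] for c in range(w)] for r in range(h)])
    assert adjusted_rand_score(truth.ravel(), seg.labels.ravel()) == 1.0
    assert seg.n_segments == 2


def test_checkerboard_exclusion_gives_singletons():
    h = w = 6
    stack = _stack_from_histories([None], h, w,
                                  {(r, c): 0 for r in range(h) for c in range(w)})
    include = np.indices((h, w)).sum(axis=0) % 2 == 0
    seg = segment_landscape(stack, include, connectivity=4)
    assert seg.n_segments == include.sum()
    assert (seg.n_pixels == 1).all()


def test_partition_and_area_conservation(small_truth):
    from swiddenscape.raster import mask_final_old_growth
    from swiddenscape.synthetic import OLD_GROWTH, simulate_stack

    stack = simulate_stack(small_truth, np.random.default_rng(3))
    include = mask_final_old_growth(small_truth.final_cover(), OLD_GROWTH)
    seg = segment_landscape(stack, include)
    assert ((seg.labels > 0) == include).all()          # partition of included pixels
    assert seg.n_pixels.sum() == include.sum()
    assert seg.area_ha.sum() == pytest.approx(include.sum() * 0.09)
    assert (seg.area_ha > 0).all()


def test_segment_mean_series_rules():
    times = np.array([2000.1, 2000.2, 2000.3])
    values = np.zeros((3, 1, 2))
    values[:, 0, 0] = 0.3
    values[:, 0, 1] = 0.5
    valid = np.ones((3, 1, 2), dtype=bool)
    valid[1, 0, 1] = False
    valid[2, 0, :] = False
    stack = SeriesStack(times, values, valid)
    single = segment_mean_series(np.array([[0, 0]]), stack)
    assert np.allclose(single.values[single.valid], 0.3)
    both = segment_mean_series(np.array([[0, 0], [0, 1]]), stack)
    assert both.values[0] == pytest.approx(0.4)      # mean of the two
    assert both.values[1] == pytest.approx(0.3)      # only first pixel valid
    assert list(both.valid) == [True, True, False]   # no pixel valid on date 3


def test_mean_series_variance_bounded_by_members(rng):
    # averaging cannot exceed the most variable member
    times = np.linspace(2000, 2005, 50)
    for _ in range(20):
        n_px = rng.integers(2, 5)
        values = rng.normal(0, rng.uniform(0.05, 0.2, size=n_px),
                            size=(50, n_px)).reshape(50, 1, n_px)
        stack = SeriesStack(times, values, np.ones_like(values, dtype=bool))
        px = np.column_stack([np.zeros(n_px, int), np.arange(n_px)])
        m = segment_mean_series(px, stack)
        assert m.values.var() <= values.reshape(50, n_px).var(axis=0).max() + 1e-12
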