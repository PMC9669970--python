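"""Raster analytics: binning, bump tracking, travel time, regression,
quiescent/active splitting and sigmoid stepping fits."""

import numpy as np
import pytest
from scipy import stats

from locint.analysis import (
    RateSeries,
    bin_rates,
    bump_trajectory,
    circular_displacement,
    circular_mean_coordinate,
    count_psr,
    fit_sigmoid,
    regress_rate_vs_time,
    split_quiescent_active,
    travel_time,
)
from locint.network import rng_for
from locint.params import InvalidArgumentError
from locint.raster import SpikeRaster
from locint.synthetic import (
    constant_cluster_raster,
    drifting_cluster_raster,
    late_surge_histogram_raster,
    periodic_raster,
    step_raster,
    wrap_cluster_raster,
)


# ---------------------------------------------------------------------------
# bin_rates
# ---------------------------------------------------------------------------

def test_periodic_neuron_rate_in_every_bin():
    raster = periodic_raster(isi_ms=10.0, duration=100.0)
    rs = bin_rates(raster, 25.0, level="neuron")
    # spike at t=0 belongs to the first bin (half-open convention)
    assert rs.rates.shape == (1, 4)
    np.testing.assert_allclose(rs.rates[0], [120.0, 80.0, 120.0, 80.0])
    assert rs.rates[0].mean() == pytest.approx(100.0)


def test_empty_raster_all_zero():
    raster = SpikeRaster(np.empty(0, int), np.empty(0), 100.0, 0.1, {"X": (0, 5)})
    rs = bin_rates(raster, 20.0, pop="X")
    assert np.all(rs.rates == 0)


def test_population_rate_is_mean_of_neuron_rates():
    raster = drifting_cluster_raster(seed=5)
    per = bin_rates(raster, 50.0, level="neuron", pop="Pyr")
    pop = bin_rates(raster, 50.0, level="population", pop="Pyr")
    np.testing.assert_allclose(pop.rates[0], per.rates.mean(axis=0), atol=1e-9)


def test_counting_conservation():
    raster = drifting_cluster_raster(seed=6)
    rs = bin_rates(raster, 25.0, level="population", pop="Pyr")
    total = rs.rates[0].sum() * 0.025 * raster.pop_size("Pyr")
    assert total == pytest.approx(raster.n_events, abs=0.5)


def test_empty_window_rejected():
    raster = periodic_raster()
    with pytest.raises(InvalidArgumentError):
        bin_rates(raster, 10.0, window=(50.0, 50.0))


# ---------------------------------------------------------------------------
# bump trajectory
# ---------------------------------------------------------------------------

def test_constant_cluster_trajectory():
    raster = constant_cluster_raster(coordinate=1000, seed=1)
    traj = bump_trajectory(raster)
    med = np.nanmedian(traj["coordinate"])
    assert med == pytest.approx(1000, abs=5)


def test_drifting_cluster_recovers_slope():
    raster = drifting_cluster_raster(start=100.0, slope=2.0, seed=2)
    traj = bump_trajectory(raster).dropna()
    # unwrap the circular coordinate before the linear fit
    c = np.unwrap(traj["coordinate"].to_numpy() * 2 * np.pi / 4000) * 4000 / (2 * np.pi)
    fit = stats.linregress(traj["time_ms"], c)
    assert fit.slope == pytest.approx(2.0, rel=0.05)


def test_wrap_point_circular_mean():
    raster = wrap_cluster_raster(seed=3)
    traj = bump_trajectory(raster).dropna()
    # cluster straddles 0/4000: circular mean near the boundary, never ~2000
    d = np.minimum(traj["coordinate"], 4000 - traj["coordinate"])
    assert np.all(d < 120)


def test_sparse_windows_undefined():
    raster = constant_cluster_raster(rate_hz=2.0, width=5, seed=4)
    traj = bump_trajectory(raster, window_ms=20.0, min_spikes=5)
    assert traj["coordinate"].isna().any()


def test_missing_coordinates_rejected():
    raster = step_raster(seed=1)  # population "E" has no coordinates
    with pytest.raises(InvalidArgumentError):
        bump_trajectory(raster, pop="E")


def test_circular_displacement_signed_shortest_arc():
    assert circular_displacement(3900.0, 100.0, 4000) == pytest.approx(200.0)
    assert circular_displacement(100.0, 3900.0, 4000) == pytest.approx(-200.0)
    cm = circular_mean_coordinate(np.array([3990, 10]), 4000)
    assert min(cm, 4000 - cm) < 1e-6  # boundary, not the diametral 2000


# ---------------------------------------------------------------------------
# travel time
# ---------------------------------------------------------------------------

def test_travel_time_matches_brute_force_on_synthetic_surge():
    raster = late_surge_histogram_raster(surge_start=600.0, seed=7)
    tt = travel_time(raster, stimulus_onset_ms=100.0)
    assert tt == pytest.approx(500.0, abs=10.0)
    # independent oracle: explicit histogram scan
    coords, times = raster.coord_of_events("Pyr")
    sel = times[coords >= 3600]
    counts, edges = np.histogram(sel, bins=np.arange(0, raster.duration + 5, 10.0))
    thr = counts.mean() + 2 * counts.std()
    first = edges[np.nonzero(counts > thr)[0][0]]
    assert tt == pytest.approx(first - 100.0)


def test_travel_time_undefined_without_crossing():
    raster = SpikeRaster(np.empty(0, int), np.empty(0), 500.0, 0.1,
                         {"Pyr": (0, 4000)}, {"Pyr": np.arange(4000)})
    with pytest.warns(UserWarning):
        assert np.isnan(travel_time(raster, 100.0))


# ---------------------------------------------------------------------------
# ramping regression
# ---------------------------------------------------------------------------

def _series(y, bin_ms=25.0, t0=100.0):
    edges = t0 + np.arange(len(y) + 1) * bin_ms
    return RateSeries(edges, np.asarray(y, dtype=float))


def test_regression_exact_line():
    t = 100.0 + np.arange(18) * 25.0 + 12.5
    slope, p = regress_rate_vs_time(_series(2.0 + 0.04 * t))
    assert slope == pytest.approx(0.04, rel=1e-9)
    assert p < 1e-20


def test_regression_constant_series():
    slope, p = regress_rate_vs_time(_series(np.full(18, 7.0)))
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert p > 0.9


def test_regression_monte_carlo_power():
    """Line + unit Gaussian noise, 18 bins, slope 0.05: recovered within
    [0.03, 0.07] and significant in >= 95% of draws."""
    rng = rng_for(123, "mc")
    t = 100.0 + np.arange(18) * 25.0 + 12.5
    hits, inside = 0, 0
    n = 400
    for _ in range(n):
        y = 2.0 + 0.05 * t + rng.normal(0, 1.0, 18)
        slope, p = regress_rate_vs_time(_series(y))
        inside += 0.03 <= slope <= 0.07
        hits += p < 0.05
    assert hits / n >= 0.95
    assert inside / n >= 0.95


def test_p_values_uniform_under_null():
    """White-noise series give uniform regression p-values (KS test)."""
    rng = rng_for(7, "null")
    ps = []
    for _ in range(1000):
        y = rng.normal(0, 1.0, 18)
        _, p = regress_rate_vs_time(_series(y))
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# quiescent/active split
# ---------------------------------------------------------------------------

def test_split_step_series():
    y = np.where(100.0 + np.arange(18) * 25.0 < 300.0, 0.0, 20.0)
    sp = split_quiescent_active(_series(y))
    assert sp.T == 300.0
    assert sp.quiescent_mean == 0.0
    assert sp.active_mean == 20.0


def test_split_constant_series_degenerate_edge():
    sp = split_quiescent_active(_series(np.full(18, 10.0)))
    assert sp.T == 100.0  # first bin already reaches the mean
    assert np.isnan(sp.quiescent_mean)


def test_split_linear_ramp_crosses_at_midpoint():
    y = np.linspace(0, 17, 18)
    sp = split_quiescent_active(_series(y))
    assert sp.T == 100.0 + 9 * 25.0  # first bin with rate >= mean (8.5)


def test_split_all_zero_flagged():
    sp = split_quiescent_active(_series(np.zeros(18)))
    assert sp.degenerate and sp.T == 100.0


# ---------------------------------------------------------------------------
# sigmoid fits / PSR counting
# ---------------------------------------------------------------------------

def _sigmoid_series(a, b, c, d, n=9, bin_ms=50.0, t0=100.0):
    t = t0 + np.arange(n) * bin_ms + bin_ms / 2
    y = c / (1 + np.exp(-a * (t - b))) + d
    return _series(y, bin_ms=bin_ms)


def test_sigmoid_selfconsistency():
    fit = fit_sigmoid(_sigmoid_series(0.05, 300.0, 15.0, 2.0))
    assert fit.success and fit.r2 > 0.999999
    assert fit.a == pytest.approx(0.05, rel=1e-3)
    assert fit.b == pytest.approx(300.0, rel=1e-3)
    assert fit.c == pytest.approx(15.0, rel=1e-3)
    assert fit.d == pytest.approx(2.0, rel=1e-3)


def test_sigmoid_recovers_planted_parameters_across_draws():
    """Noiseless random sigmoids are recovered to < 1% relative error, and
    the fit is deterministic (fixed multi-start, no RNG)."""
    rng = rng_for(99, "sigmoid")
    for _ in range(100):
        a = rng.uniform(0.01, 0.2)
        b = rng.uniform(200.0, 450.0)
        c = rng.uniform(5.0, 40.0)
        d = rng.uniform(0.0, 5.0)
        series = _sigmoid_series(a, b, c, d)
        f1 = fit_sigmoid(series)
        assert f1.success
        assert abs(f1.c - c) / c < 0.01
        assert abs(f1.d - d) < max(0.01 * c, 0.05)
        f2 = fit_sigmoid(series)
        assert (f1.a, f1.b, f1.c, f1.d) == (f2.a, f2.b, f2.c, f2.d)


def test_hard_step_classified_as_stepping():
    y = np.where(np.arange(9) < 4, 0.0, 10.0)
    fit = fit_sigmoid(_series(y, bin_ms=50.0))
    assert fit.success and fit.r2 >= 0.85


def test_constant_series_excluded():
    fit = fit_sigmoid(_series(np.full(9, 3.0), bin_ms=50.0))
    assert not fit.success and fit.r2 == 0.0


def test_count_psr_zero_for_constant_population():
    series = RateSeries(100.0 + np.arange(10) * 50.0, np.full((5, 9), 4.0))
    tab = count_psr({(0.1, 0.15): series})
    assert int(tab["psr_count"].iloc[0]) == 0


def test_count_psr_detects_planted_steppers():
    raster = step_raster(n_neurons=20, step_time=300.0, rate_high=40.0, seed=11, regular=True)
    rs = bin_rates(raster, 50.0, window=(100.0, 550.0), level="neuron", pop="E")
    tab = count_psr({(0.1, 0.15): rs})
    assert int(tab["psr_count"].iloc[0]) >= 18  # noise-free steps all found
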