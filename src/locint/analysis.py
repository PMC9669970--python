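"""Raster analytics: rates, bump tracking, travel time, ramping and stepping.

All statistics operate on :class:`locint.raster.SpikeRaster` objects (or on
plain rate series) and use half-open time bins ``[start, stop)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import InvalidArgumentError
from .raster import SpikeRaster


@dataclass
class RateSeries:
    """Firing rates (Hz) in contiguous non-overlapping bins.

    ``rates`` has shape (n_series, n_bins): one row per neuron, or a
    single row for a population mean.
    """

    edges: np.ndarray  # bin edges, ms, length n_bins + 1
    rates: np.ndarray  # Hz
    labels: list | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_ms(self) -> float:
        return float(self.edges[1] - self.edges[0])


def bin_rates(
    raster: SpikeRaster,
    bin_ms: float,
    window: tuple[float, float] | None = None,
    level: str = "neuron",
    pop: str | None = None,
) -> RateSeries:
    """Spike counts per bin converted to rates (Hz).

    ``level="neuron"`` returns one row per neuron of ``pop``;
    ``level="population"`` returns a single row of population-mean rates
    (count / (bin width x number of neurons)).  Spikes on a bin edge
    belong to the bin starting there (half-open bins).
    """
    if bin_ms <= 0:
        raise InvalidArgumentError("bin_ms must be positive")
    if pop is None:
        if len(raster.pops) != 1:
            raise InvalidArgumentError("pop must be named for multi-population rasters")
        pop = next(iter(raster.pops))
    if window is None:
        window = (0.0, raster.duration)
    t0, t1 = window
    if not t0 < t1:
        raise InvalidArgumentError("empty analysis window")
    n_bins = int(round((t1 - t0) / bin_ms))
    edges = t0 + np.arange(n_bins + 1) * bin_ms
    local, times = raster.select(pop)
    n_neurons = raster.pop_size(pop)
    keep = (times >= t0) & (times < edges[-1])
    local, times = local[keep], times[keep]
    bin_idx = np.floor((times - t0) / bin_ms).astype(np.int64)
    if level == "neuron":
        counts = np.zeros((n_neurons, n_bins))
        np.add.at(counts, (local, bin_idx), 1.0)
        return RateSeries(edges, counts / (bin_ms / 1000.0), labels=list(range(n_neurons)))
    if level == "population":
        counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
        return RateSeries(edges, counts[None, :] / (n_neurons * bin_ms / 1000.0), labels=[pop])
    raise InvalidArgumentError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# Bump tracking
# ---------------------------------------------------------------------------

def circular_mean_coordinate(coords: np.ndarray, lattice_size: int) -> float:
    """Circular mean of lattice coordinates (0-based), in [0, lattice_size)."""
    ang = 2.0 * np.pi * np.asarray(coords, dtype=float) / lattice_size
    mean_ang = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return (mean_ang / (2.0 * np.pi) * lattice_size) % lattice_size


def circular_displacement(c0: float, c1: float, lattice_size: int) -> float:
    """Signed circular displacement from c0 to c1 in (-L/2, L/2]."""
    d = (c1 - c0) % lattice_size
    if d > lattice_size / 2:
        d -= lattice_size
    return d


def bump_trajectory(
    raster: SpikeRaster,
    window_ms: float = 20.0,
    pop: str = "Pyr",
    min_spikes: int = 5,
) -> pd.DataFrame:
    """Circular-mean bump coordinate per time window.

    Windows with fewer than ``min_spikes`` spikes yield NaN (no defined
    bump).  Requires the population to carry lattice coordinates.
    """
    if pop not in raster.coords or raster.coords[pop] is None:
        raise InvalidArgumentError(f"population {pop!r} carries no coordinates")
    L = raster.pop_size(pop)
    coord_of, times = raster.coord_of_events(pop)
    n_win = int(math.floor(raster.duration / window_ms))
    out_t = np.arange(n_win) * window_ms + window_ms / 2.0
    out_c = np.full(n_win, np.nan)
    idx = np.floor(times / window_ms).astype(np.int64)
    for w in range(n_win):
        sel = coord_of[idx == w]
        if len(sel) >= min_spikes:
            out_c[w] = circular_mean_coordinate(sel, L)
    return pd.DataFrame({"time_ms": out_t, "coordinate": out_c})


def travel_time(
    raster: SpikeRaster,
    stimulus_onset_ms: float,
    pop: str = "Pyr",
    n_last: int = 400,
    bin_ms: float = 10.0,
    scan_from_ms: float | None = None,
) -> float:
    """Bump travel time to the far end of the lattice (ms).

    Histograms the spikes of the ``n_last`` highest-coordinate cells in
    10-ms bins over the whole simulation and returns the start of the
    first bin whose count exceeds mean + 2 SD of all bins, relative to
    stimulus onset.  ``scan_from_ms`` restricts the crossing search to
    later bins (the threshold itself is still computed from all bins), to
    skip the start-up transient of a fresh network.  Returns NaN when no
    bin crosses (no arrival).
    """
    if pop not in raster.coords or raster.coords[pop] is None:
        raise InvalidArgumentError(f"population {pop!r} carries no coordinates")
    coord_of, times = raster.coord_of_events(pop)
    L = raster.pop_size(pop)
    sel = coord_of >= L - n_last
    edges = np.arange(0.0, raster.duration + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(times[sel], bins=edges)
    thr = counts.mean() + 2.0 * counts.std()
    above = np.nonzero(counts > thr)[0]
    if scan_from_ms is not None:
        above = above[edges[above] >= scan_from_ms]
    if len(above) == 0:
        warnings.warn("no bin exceeds mean + 2 SD; travel time undefined")
        return float("nan")
    return float(edges[above[0]] - stimulus_onset_ms)


# ---------------------------------------------------------------------------
# Ramping / stepping statistics
# ---------------------------------------------------------------------------

def regress_rate_vs_time(series: RateSeries, row: int = 0) -> tuple[float, float]:
    """OLS slope of rate on bin-center time with its two-sided p-value."""
    if series.rates.shape[1] < 3:
        raise InvalidArgumentError("need at least 3 bins for a regression")
    t = series.centers
    if np.ptp(t) == 0:
        raise InvalidArgumentError("zero-variance time axis")
    y = series.rates[row]
    res = stats.linregress(t, y)
    p = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), float(p)


def count_time_correlated(series: RateSeries, alpha: float = 0.05) -> int:
    """Number of rows whose rate is significantly correlated with time."""
    n = 0
    for i in range(series.rates.shape[0]):
        if np.ptp(series.rates[i]) == 0:
            continue
        _, p = regress_rate_vs_time(series, row=i)
        if p < alpha:
            n += 1
    return n


@dataclass(frozen=True)
class ActivitySplit:
    """Quiescent/active split of one rate time course.

    ``T`` is the start of the first bin whose rate reaches the mean over
    all bins; the quiescent window is [window start, T), the active
    window [T, window stop].  ``degenerate`` flags all-zero series.
    """

    T: float
    quiescent_mean: float
    active_mean: float
    degenerate: bool = False


def split_quiescent_active(series: RateSeries, row: int = 0) -> ActivitySplit:
    y = series.rates[row]
    starts = series.edges[:-1]
    mean = y.mean()
    if np.all(y == 0):
        return ActivitySplit(T=float(starts[0]), quiescent_mean=0.0,
                             active_mean=0.0, degenerate=True)
    k = int(np.nonzero(y >= mean)[0][0])  # ties cross upward
    T = float(starts[k])
    q = float(y[:k].mean()) if k > 0 else float("nan")
    a = float(y[k:].mean())
    return ActivitySplit(T=T, quiescent_mean=q, active_mean=a)


@dataclass(frozen=True)
class SigmoidFit:
    """Least-squares sigmoid fit ``c / (1 + exp(-a (x - b))) + d``."""

    a: float  # steepness, 1/ms
    b: float  # transition time, ms
    c: float  # amplitude, Hz
    d: float  # offset, Hz
    r2: float
    success: bool

    def predict(self, x):
        return self.c / (1.0 + np.exp(-self.a * (np.asarray(x) - self.b))) + self.d


def _sigmoid(x, a, b, c, d):
    return c / (1.0 + np.exp(np.clip(-a * (x - b), -500, 500))) + d


def fit_sigmoid(series: RateSeries, row: int = 0) -> SigmoidFit:
    """Fit one rate time course to the four-parameter sigmoid.

    Deterministic multi-start nonlinear least squares: the offset starts
    at the minimum rate, the amplitude at the range, the transition time
    at the quiescent/active split, and the steepness at each of
    {0.01, 0.05, 0.2}/ms; the best R-squared wins.  Constant series have
    zero total variance; their R-squared is defined as 0 and the fit is
    flagged unsuccessful.
    """
    y = series.rates[row]
    if len(y) < 5:
        raise InvalidArgumentError("need at least 5 bins for a sigmoid fit")
    x = series.centers
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return SigmoidFit(0.0, 0.0, 0.0, float(y[0]) if len(y) else 0.0, 0.0, False)
    d0 = float(y.min())
    c0 = float(y.max() - y.min())
    b0 = split_quiescent_active(series, row=row).T
    best = None
    bounds = ([1e-6, x[0] - 10 * series.bin_ms, 0.0, -np.inf],
              [np.inf, x[-1] + 10 * series.bin_ms, np.inf, np.inf])
    for a0 in (0.01, 0.05, 0.2):
        try:
            popt, _ = optimize.curve_fit(
                _sigmoid, x, y, p0=[a0, b0, max(c0, 1e-6), d0],
                bounds=bounds, maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _sigmoid(x, *popt)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        if best is None or r2 > best[1]:
            best = (popt, r2)
        if r2 > 0.999:  # already essentially exact; further starts can't help
            break
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, -np.inf, False)
    (a, b, c, d), r2 = best
    return SigmoidFit(float(a), float(b), float(c), float(d), r2, True)


def count_psr(
    series_by_cell: dict, r2_threshold: float = 0.85
) -> pd.DataFrame:
    """Potential-stepping-response counts over a parameter grid.

    ``series_by_cell`` maps grid keys (e.g. ``(p0, p_conn)``) to per-neuron
    :class:`RateSeries` (50-ms bins).  A neuron is a PSR neuron when its
    sigmoid fit succeeds with R-squared >= the threshold.
    """
    rows = []
    for key, series in series_by_cell.items():
        n = series.rates.shape[0]
        count = 0
        for i in range(n):
            fit = fit_sigmoid(series, row=i)
            if fit.success and fit.r2 >= r2_threshold:
                count += 1
        p0, p_conn = key if isinstance(key, tuple) else (key, np.nan)
        rows.append({"p0": p0, "p_conn": p_conn, "psr_count": count,
                     "n_neurons": n, "psr_ratio": count / n if n else np.nan})
    return pd.DataFrame(rows)
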