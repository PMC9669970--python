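"""Deterministic synthetic rasters for testing the analysis suite.

These generators construct spike rasters with known ground truth (exact
rates, drift slopes, step times), so every analysis statistic can be
checked against the construction rather than against another simulation.
"""

from __future__ import annotations

import numpy as np

from .network import rng_for
from .raster import SpikeRaster


def periodic_raster(
    isi_ms: float = 10.0, duration: float = 100.0, n_neurons: int = 1
) -> SpikeRaster:
    """Every neuron spikes strictly periodically starting at t = 0."""
    t = np.arange(0.0, duration, isi_ms)
    times = np.tile(t, n_neurons)
    gids = np.repeat(np.arange(n_neurons), len(t))
    order = np.argsort(times, kind="stable")
    return SpikeRaster(
        gids=gids[order],
        times=times[order],
        duration=duration,
        dt=0.1,
        pops={"Pyr": (0, n_neurons)},
        coords={"Pyr": np.arange(n_neurons)},
    )


def constant_cluster_raster(
    coordinate: int = 1000,
    lattice: int = 4000,
    rate_hz: float = 50.0,
    width: int = 20,
    duration: float = 500.0,
    seed: int = 0,
) -> SpikeRaster:
    """A stationary bump: Poisson spikes confined to one coordinate patch."""
    rng = rng_for(seed, "synthetic:constant")
    lo = coordinate - width // 2
    n_events = rng.poisson(rate_hz * width * duration / 1000.0)
    gids = (lo + rng.integers(0, width, n_events)) % lattice
    times = np.sort(np.round(rng.uniform(0, duration, n_events), 1))
    return SpikeRaster(
        gids=gids, times=times, duration=duration, dt=0.1,
        pops={"Pyr": (0, lattice)}, coords={"Pyr": np.arange(lattice)},
    )


def drifting_cluster_raster(
    start: float = 100.0,
    slope: float = 2.0,  # coordinates per ms
    lattice: int = 4000,
    rate_per_ms: float = 3.0,
    width: int = 20,
    duration: float = 500.0,
    seed: int = 0,
) -> SpikeRaster:
    """A cluster whose center moves as ``start + slope * t`` (mod lattice)."""
    rng = rng_for(seed, "synthetic:drift")
    n = rng.poisson(rate_per_ms * duration)
    times = np.sort(np.round(rng.uniform(0, duration, n), 1))
    centers = start + slope * times
    gids = (np.round(centers + rng.uniform(-width / 2, width / 2, n)).astype(int)) % lattice
    return SpikeRaster(
        gids=gids, times=times, duration=duration, dt=0.1,
        pops={"Pyr": (0, lattice)}, coords={"Pyr": np.arange(lattice)},
    )


def wrap_cluster_raster(
    lattice: int = 4000, duration: float = 100.0, seed: int = 0
) -> SpikeRaster:
    """Spikes split across the periodic wrap point (near 0 and lattice-1)."""
    rng = rng_for(seed, "synthetic:wrap")
    n = 200
    gids = np.where(rng.random(n) < 0.5, rng.integers(lattice - 60, lattice, n),
                    rng.integers(0, 60, n))
    times = np.sort(np.round(rng.uniform(0, duration, n), 1))
    return SpikeRaster(
        gids=gids, times=times, duration=duration, dt=0.1,
        pops={"Pyr": (0, lattice)}, coords={"Pyr": np.arange(lattice)},
    )


def step_raster(
    n_neurons: int = 20,
    step_time: float = 300.0,
    rate_low: float = 0.0,
    rate_high: float = 10.0,
    duration: float = 650.0,
    seed: int = 0,
    regular: bool = False,
) -> SpikeRaster:
    """Neurons silent (or at a low rate) before ``step_time`` and active at
    ``rate_high`` afterwards: an idealized stepping response.  With
    ``regular=True`` the active phase fires clock-regularly (per-neuron
    phase offsets), giving noise-free binned rates."""
    rng = rng_for(seed, "synthetic:step")
    gids, times = [], []
    for i in range(n_neurons):
        if regular:
            isi = 1000.0 / rate_high
            t = np.arange(step_time + (i % 10) * isi / 10.0, duration, isi)
            times.append(np.round(t, 1))
            gids.append(np.full(len(t), i, dtype=int))
            continue
        for (a, b, r) in ((0.0, step_time, rate_low), (step_time, duration, rate_high)):
            n = rng.poisson(r * (b - a) / 1000.0)
            times.append(np.round(rng.uniform(a, b, n), 1))
            gids.append(np.full(n, i, dtype=int))
    gids = np.concatenate(gids)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(
        gids=gids[order], times=times[order], duration=duration, dt=0.1,
        pops={"E": (0, n_neurons)},
    )


def late_surge_histogram_raster(
    baseline_rate: float = 200.0,  # Hz summed over the far-end cells
    surge_rate: float = 5000.0,
    surge_start: float = 600.0,
    surge_stop: float = 700.0,
    lattice: int = 4000,
    n_last: int = 400,
    duration: float = 1000.0,
    seed: int = 0,
) -> SpikeRaster:
    """Low baseline counts in the highest-coordinate cells plus one late
    surge block: a travel-time test case with a known crossing bin."""
    rng = rng_for(seed, "synthetic:surge")
    lo = lattice - n_last
    segs = []
    for (a, b, r) in ((0.0, duration, baseline_rate), (surge_start, surge_stop, surge_rate)):
        n = rng.poisson(r * (b - a) / 1000.0)
        segs.append((np.round(rng.uniform(a, b, n), 1), lo + rng.integers(0, n_last, n)))
    times = np.concatenate([s[0] for s in segs])
    gids = np.concatenate([s[1] for s in segs])
    order = np.argsort(times, kind="stable")
    return SpikeRaster(
        gids=gids[order], times=times[order], duration=duration, dt=0.1,
        pops={"Pyr": (0, lattice)}, coords={"Pyr": np.arange(lattice)},
    )
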