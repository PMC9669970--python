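"""Spike rasters and their plain-text interchange format.

A raster is the full event record of a run: (global neuron id, population
label, spike time).  The on-disk format is headered tab-delimited text with
columns ``neuron_id``, ``population``, ``time_ms`` (fixed point at 0.1 ms),
sorted by time, preceded by ``#``-prefixed metadata lines that make the
file self-describing (duration, dt, population layout).  Reading a written
file reproduces the raster bit-exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import InvalidArgumentError


@dataclass
class SpikeRaster:
    """Spike events of one simulation run.

    ``gids`` and ``times`` are parallel arrays sorted by time.  ``pops``
    maps population name to (start, size) in the global id space;
    ``coords`` optionally maps population name to 0-based lattice
    coordinates (one per neuron).
    """

    gids: np.ndarray
    times: np.ndarray
    duration: float
    dt: float
    pops: dict[str, tuple[int, int]]
    coords: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gids = np.asarray(self.gids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.gids) != len(self.times):
            raise InvalidArgumentError("gids and times must align")

    # -- selection --------------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.times)

    def pop_size(self, pop: str) -> int:
        return self.pops[pop][1]

    def select(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (local neuron index, time) for one population."""
        start, size = self.pops[pop]
        mask = (self.gids >= start) & (self.gids < start + size)
        return self.gids[mask] - start, self.times[mask]

    def spike_count(self, pop: str, t0: float | None = None, t1: float | None = None) -> int:
        _, t = self.select(pop)
        if t0 is not None:
            t = t[t >= t0]
        if t1 is not None:
            t = t[t < t1]
        return len(t)

    def labels(self) -> np.ndarray:
        names = np.array(list(self.pops.keys()))
        starts = np.array([v[0] for v in self.pops.values()])
        idx = np.searchsorted(starts, self.gids, side="right") - 1
        return names[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"neuron_id": self.gids, "population": self.labels(), "time_ms": self.times}
        )

    def coord_of_events(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """(coordinate, time) of every spike of a coordinate-bearing population."""
        if pop not in self.coords:
            raise InvalidArgumentError(f"population {pop!r} carries no coordinates")
        local, t = self.select(pop)
        return self.coords[pop][local], t


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_raster(raster: SpikeRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={raster.duration:.1f} dt_ms={raster.dt:g}\n")
        for name, (start, size) in raster.pops.items():
            has_coords = 1 if name in raster.coords else 0
            fh.write(f"# population {name} start={start} size={size} coords={has_coords}\n")
        fh.write("neuron_id\tpopulation\ttime_ms\n")
        labels = raster.labels()
        buf = io.StringIO()
        for g, p, t in zip(raster.gids, labels, raster.times):
            buf.write(f"{g}\t{p}\t{t:.1f}\n")
        fh.write(buf.getvalue())


def read_raster(path) -> SpikeRaster:
    duration, dt = 0.0, 0.1
    pops: dict[str, tuple[int, int]] = {}
    coords: dict[str, np.ndarray] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            parts = line[1:].split()
            if parts and parts[0].startswith("duration_ms="):
                duration = float(parts[0].split("=")[1])
                dt = float(parts[1].split("=")[1])
            elif parts and parts[0] == "population":
                name = parts[1]
                kv = dict(p.split("=") for p in parts[2:])
                pops[name] = (int(kv["start"]), int(kv["size"]))
                if int(kv.get("coords", 0)):
                    # builders assign coordinate = local index; regenerate
                    coords[name] = np.arange(int(kv["size"]))
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    return SpikeRaster(
        gids=df["neuron_id"].to_numpy(),
        times=df["time_ms"].to_numpy(),
        duration=duration,
        dt=dt,
        pops=pops,
        coords=coords,
    )


def validate_raster(raster: SpikeRaster, t_ref_abs: float = 0.0) -> None:
    """Check raster invariants: times in range, per-neuron ISIs >= t_ref_abs."""
    if raster.n_events == 0:
        return
    if raster.times.min() < 0 or raster.times.max() > raster.duration:
        raise InvalidArgumentError("spike times outside [0, duration]")
    order = np.lexsort((raster.times, raster.gids))
    g, t = raster.gids[order], raster.times[order]
    same = g[1:] == g[:-1]
    isi = t[1:] - t[:-1]
    if np.any(same & (isi < t_ref_abs - 1e-9)):
        raise InvalidArgumentError("inter-spike interval below absolute refractory period")
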