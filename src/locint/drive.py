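"""External drive: Poisson spike-train inputs and DC current steps.

Background and stimulus inputs to the integrators are independent Poisson
spike trains delivered through static synapses of a given weight.  Each
:class:`PoissonDrive` entry owns a labeled random stream derived from the
run's master seed, so individual drive components are reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import rng_for
from .params import InvalidArgumentError


@dataclass
class PoissonDrive:
    """Independent Poisson input to a set of target neurons.

    Every target receives its own train at ``rate`` Hz; each event adds
    ``weight`` pA to the target's synaptic current.  Active on
    ``start <= t < stop`` (ms).
    """

    targets: np.ndarray  # global neuron ids
    rate: float  # Hz, per target
    weight: float  # pA
    start: float  # ms
    stop: float  # ms
    label: str
    rate_sd_frac: float = 0.0  # per-target Gaussian rate heterogeneity (CV)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if self.rate < 0:
            raise InvalidArgumentError(f"negative Poisson rate in {self.label!r}")
        if not self.start < self.stop:
            raise InvalidArgumentError(f"start must precede stop in {self.label!r}")

    def target_rates(self, seed: int) -> np.ndarray:
        """Per-target rates (Hz): quenched one-sided (downward half-normal)
        heterogeneity below the nominal rate, reproducible from the master
        seed.  Spreading operating points strictly downward desynchronizes
        a population whose nominal background sits at rheobase without
        pushing any cell above it."""
        from .network import rng_for

        if self.rate_sd_frac == 0.0:
            return np.full(len(self.targets), self.rate)
        rng = rng_for(seed, f"rates:{self.label}")
        z = np.abs(rng.normal(0.0, self.rate_sd_frac, len(self.targets)))
        return np.clip(self.rate * (1.0 - z), 0.0, None)


@dataclass
class CurrentStep:
    """Constant current injection (pA) over [start, stop) ms.  Deterministic."""

    targets: np.ndarray
    amplitude: float
    start: float
    stop: float
    label: str = "dc"

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if not self.start < self.stop:
            raise InvalidArgumentError("start must precede stop")


@dataclass
class DriveSchedule:
    poisson: list[PoissonDrive] = field(default_factory=list)
    currents: list[CurrentStep] = field(default_factory=list)

    def add_poisson(
        self, targets, rate, weight, start, stop, label, rate_sd_frac=0.0
    ) -> "DriveSchedule":
        self.poisson.append(
            PoissonDrive(targets, rate, weight, start, stop, label, rate_sd_frac)
        )
        return self

    def add_current(self, targets, amplitude, start, stop, label="dc") -> "DriveSchedule":
        self.currents.append(CurrentStep(targets, amplitude, start, stop, label))
        return self

    @property
    def max_stop(self) -> float:
        stops = [e.stop for e in self.poisson] + [e.stop for e in self.currents]
        return max(stops) if stops else 0.0


def generate_poisson_drive(
    schedule: DriveSchedule, duration: float, dt: float, seed: int
) -> dict[str, list[np.ndarray]]:
    """Realize the Poisson entries of a schedule as explicit spike trains.

    Events are discretized to the simulation grid: for each step the event
    count is Poisson with mean ``rate * dt`` and all events of a step are
    placed at the step start.  The per-entry random streams and their
    consumption order are identical to the ones the network engine uses, so
    the trains returned here are exactly the trains a simulation with the
    same master seed injects.

    Returns a dict mapping entry label to a list of per-target spike-time
    arrays (ms).
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    out: dict[str, list[np.ndarray]] = {}
    for entry in schedule.poisson:
        rng = rng_for(seed, f"poisson:{entry.label}")
        lam = entry.target_rates(seed) * dt / 1000.0
        n_t = len(entry.targets)
        trains: list[list[float]] = [[] for _ in range(n_t)]
        start_step = int(round(entry.start / dt))
        stop_step = min(int(round(entry.stop / dt)), n_steps)
        for step in range(start_step, stop_step):
            counts = rng.poisson(lam)
            t = step * dt
            for i in np.nonzero(counts)[0]:
                trains[i].extend([t] * counts[i])
        out[entry.label] = [np.array(tr) for tr in trains]
    return out
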