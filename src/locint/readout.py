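"""Decision readout through gradient connections.

The position of the bump on the ring is converted into a firing rate by
"gradient" projections whose connection probability grows linearly with
the presynaptic coordinate, ``p(n) = p0 * n / N``: the farther the bump
has traveled (the more evidence accumulated), the more readout synapses
it drives.  Two readout circuits are modeled:

* a two-integrator race (2-choice decision): each integrator excites the
  E cells of its own readout population and the I cells of the opposite
  one; the difference of the two readout rates is the decision variable;
* a single integrator with one recurrently connected E population, used
  to study ramping versus stepping time courses of the decision variable.

Readout runs replay a previously recorded integrator raster through the
gradient synapses (the integrator receives no feedback from the readout,
so this is exact), which makes parameter sweeps over ``p0``/``p_conn``
cheap: one integrator simulation serves a whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drive import DriveSchedule
from .engine import ReplaySource, run_network
from .network import NetworkGraph, bernoulli_pairs, rng_for
from .params import DEFAULT_NEURON, DELAY_DEFAULT, InvalidArgumentError, SynapseSpec
from .raster import SpikeRaster


@dataclass(frozen=True)
class GradientSpec:
    """Coordinate-weighted projection probability ``p0 * n / lattice_size``."""

    p0: float
    lattice_size: int = 4000

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise InvalidArgumentError("p0 must lie in [0, 1]")


def gradient_probability(n: int, spec: GradientSpec) -> float:
    """Connection probability of the Pyr cell with 1-based coordinate ``n``."""
    if not 1 <= n <= spec.lattice_size:
        raise InvalidArgumentError(f"coordinate {n} outside 1..{spec.lattice_size}")
    return spec.p0 * n / spec.lattice_size


@dataclass(frozen=True)
class ReadoutSpec:
    """Sizes, probabilities and synaptic strengths of one readout circuit.

    The integrator-to-readout and readout-internal strengths are not
    constrained by the circuit's printed parameters; the defaults were
    calibrated (see ``scripts/calibrate_readout.py``) so that the
    population rate ramps across p0 = 0.1..1.0 and the stepping regime
    exists around p_conn = 0.15-0.25.
    """

    n_excitatory: int = 400
    n_inhibitory: int = 100
    p_conn: float = 0.15  # recurrent E->E probability (single-readout mode)
    w_integrator_e: float = 0.03  # pA, integrator Pyr -> own-readout E
    w_integrator_i: float = 0.03  # pA, integrator Pyr -> opposite-readout I
    w_i_e: float = -0.4  # pA, I -> E within a readout
    w_e_e: float = 0.1  # pA, recurrent E -> E
    ext_rate: float = 200.0  # Hz background to every readout neuron
    ext_weight: float = 1.3  # pA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_conn <= 1.0:
            raise InvalidArgumentError("p_conn must lie in [0, 1]")


def _gradient_pairs(
    rng: np.random.Generator, gradient: GradientSpec, n_post: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(p(n)) links from every lattice coordinate to every target."""
    p = gradient.p0 * (np.arange(1, gradient.lattice_size + 1) / gradient.lattice_size)
    mask = rng.random((gradient.lattice_size, n_post)) < p[:, None]
    pre, post = np.nonzero(mask)
    return pre, post


def _replay_from(
    raster: SpikeRaster,
    pre: np.ndarray,
    post_gids: np.ndarray,
    weight: float,
    n_pre: int,
    pop: str = "Pyr",
    label: str = "gradient",
) -> ReplaySource:
    order = np.argsort(pre, kind="stable")
    pre_s, post_s = pre[order], post_gids[order]
    indptr = np.searchsorted(pre_s, np.arange(n_pre + 1))
    local, times = raster.select(pop)
    return ReplaySource(
        n_pre=n_pre,
        pre_ids=local,
        times=times,
        indptr=indptr.astype(np.int64),
        post_gids=post_s.astype(np.int32),
        weights=np.full(len(post_s), float(weight)),
        delay=DELAY_DEFAULT,
        label=label,
    )


def build_single_readout(
    spec: ReadoutSpec, p_conn: float | None = None, seed: int = 0
) -> NetworkGraph:
    """One excitatory readout population with recurrent E->E synapses."""
    p_conn = spec.p_conn if p_conn is None else p_conn
    if not 0.0 <= p_conn <= 1.0:
        raise InvalidArgumentError("p_conn must lie in [0, 1]")
    net = NetworkGraph()
    net.add_population("E", spec.n_excitatory, DEFAULT_NEURON)
    if p_conn > 0:
        rng = rng_for(seed, "conn:E->E")
        pi, pj = bernoulli_pairs(rng, spec.n_excitatory, spec.n_excitatory,
                                 p_conn, no_autapse=True)
        net.connect("E->E", "E", "E", pi, pj,
                    np.full(len(pi), spec.w_e_e), SynapseSpec(weight=spec.w_e_e))
    return net


def run_single_readout(
    integrator_raster: SpikeRaster,
    gradient: GradientSpec,
    spec: ReadoutSpec,
    seed: int,
    p_conn: float | None = None,
    duration: float | None = None,
    dt: float = 0.1,
) -> SpikeRaster:
    """Drive one recurrent E readout population from a stored integrator run.

    The integrator's Pyr spikes are replayed through freshly drawn
    gradient synapses; every E cell additionally receives the 200-Hz
    external drive.  Returns the readout raster (population ``"E"``).
    """
    duration = integrator_raster.duration if duration is None else duration
    net = build_single_readout(spec, p_conn=p_conn, seed=seed)
    e_gids = net.populations["E"].gids
    rng = rng_for(seed, "conn:gradient")
    pre, post = _gradient_pairs(rng, gradient, spec.n_excitatory)
    replay = _replay_from(integrator_raster, pre, e_gids[post],
                          spec.w_integrator_e, gradient.lattice_size)
    drive = DriveSchedule()
    drive.add_poisson(e_gids, spec.ext_rate, spec.ext_weight, 0.0, duration, "ext:E")
    return run_network(net, drive, duration, dt=dt, seed=seed, replay=(replay,))


def build_race_readout(spec: ReadoutSpec) -> NetworkGraph:
    """Two E/I readout populations; I cells inhibit the E cells beside them."""
    net = NetworkGraph()
    for k in (1, 2):
        net.add_population(f"E{k}", spec.n_excitatory, DEFAULT_NEURON)
        net.add_population(f"I{k}", spec.n_inhibitory, DEFAULT_NEURON)
    return net


def run_race(
    raster1: SpikeRaster,
    raster2: SpikeRaster,
    gradient: GradientSpec,
    spec: ReadoutSpec,
    seed: int,
    duration: float | None = None,
    dt: float = 0.1,
):
    """Two-integrator race: each integrator excites its own E population and
    the I cells of the opposite readout, which inhibit that readout's E
    cells.  Returns ``(readout raster, rate-difference DataFrame)`` where
    the difference trace is mean E1 rate - mean E2 rate in 25-ms bins.
    """
    duration = min(raster1.duration, raster2.duration) if duration is None else duration
    net = build_race_readout(spec)
    for k in (1, 2):
        ei, ii = net.populations[f"E{k}"], net.populations[f"I{k}"]
        rng = rng_for(seed, f"conn:I{k}->E{k}")
        pi, pj = bernoulli_pairs(rng, ii.size, ei.size, 0.5)
        net.connect(f"I{k}->E{k}", f"I{k}", f"E{k}", pi, pj,
                    np.full(len(pi), spec.w_i_e), SynapseSpec(weight=spec.w_i_e))
    replays = []
    for k, src in ((1, raster1), (2, raster2)):
        opp = 2 if k == 1 else 1
        rng = rng_for(seed, f"conn:gradient:E{k}")
        pre, post = _gradient_pairs(rng, gradient, spec.n_excitatory)
        replays.append(_replay_from(src, pre, net.populations[f"E{k}"].gids[post],
                                    spec.w_integrator_e, gradient.lattice_size,
                                    label=f"grad:E{k}"))
        rng = rng_for(seed, f"conn:gradient:I{opp}")
        pre, post = _gradient_pairs(rng, gradient, spec.n_inhibitory)
        replays.append(_replay_from(src, pre, net.populations[f"I{opp}"].gids[post],
                                    spec.w_integrator_i, gradient.lattice_size,
                                    label=f"grad:I{opp}"))
    drive = DriveSchedule()
    for pop in ("E1", "I1", "E2", "I2"):
        drive.add_poisson(net.populations[pop].gids, spec.ext_rate,
                          spec.ext_weight, 0.0, duration, f"ext:{pop}")
    raster = run_network(net, drive, duration, dt=dt, seed=seed, replay=replays)
    diff = rate_difference_trace(raster, bin_ms=25.0)
    return raster, diff


def rate_difference_trace(raster: SpikeRaster, bin_ms: float = 25.0) -> pd.DataFrame:
    """Mean E1 minus mean E2 rate (Hz) in non-overlapping bins."""
    from .analysis import bin_rates

    r1 = bin_rates(raster, bin_ms, level="population", pop="E1")
    r2 = bin_rates(raster, bin_ms, level="population", pop="E2")
    return pd.DataFrame(
        {
            "time_ms": r1.centers,
            "rate_e1": r1.rates[0],
            "rate_e2": r2.rates[0],
            "difference": r1.rates[0] - r2.rates[0],
        }
    )


def decision_onset(
    diff: pd.DataFrame,
    threshold_hz: float = 5.0,
    sustain_bins: int = 4,
) -> float:
    """Time of the first 25-ms bin where the rate difference exceeds the
    threshold and stays positive for the following bins; NaN if never."""
    d = diff["difference"].to_numpy()
    t = diff["time_ms"].to_numpy()
    for i in range(len(d) - sustain_bins + 1):
        if d[i] > threshold_hz and np.all(d[i : i + sustain_bins] > 0):
            return float(t[i])
    return float("nan")
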