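"""Discrete location-code integrator: 17 Pyr-SST populations plus 2 PV pools.

The network stores accumulated evidence as the index of the currently
active pyramidal population.  Within each of the 17 populations the Pyr
cells are all-to-all coupled through *depressing* synapses (the motor of
propagation: a population exhausts its own recurrent drive and hands
activity to the next), and each population projects weakly and
unidirectionally to the next one, with a periodic boundary (population 17
feeds population 1).  PV1 provides global feedback inhibition driven by
all Pyr cells (winner-take-all), PV2 provides stimulus-driven feedforward
inhibition that silences the SST cells while evidence is present, and SST
cells - once released from PV inhibition during a temporal gap - laterally
inhibit every *other* population, freezing the active population in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .drive import DriveSchedule
from .engine import run_network
from .network import (
    NetworkGraph,
    bernoulli_pairs,
    jittered_weights,
    rng_for,
)
from .params import (
    DELAY_DEFAULT,
    TAU_REC_DISCRETE,
    U_DEPRESSION,
    InvalidArgumentError,
    NeuronParams,
    SynapseSpec,
)

VARIANTS = ("default", "static_synapses", "no_pv1_feedback")


@dataclass(frozen=True)
class DiscreteConfig:
    """Structural and drive parameters of the discrete integrator."""

    n_populations: int = 17
    pyr_per_pop: int = 400
    #: SST cells per population.  The circuit description is internally
    #: inconsistent (a per-population count of 16 versus a total of 544 =
    #: 17 x 32); the 32-per-population reading is the default because the
    #: doubled SST pool silences PV1 reliably during a gap, which is what
    #: keeps the holding population alive until the evidence returns.
    sst_per_pop: int = 32
    pv_count: int = 1088  # per PV population (two populations)

    # connection table: probability, mean weight (pA)
    p_pyr_pyr_within: float = 1.0
    w_pyr_pyr_within: float = 1.8
    p_pyr_sst_within: float = 0.4
    w_pyr_sst_within: float = 0.96
    # PV1 self-inhibition is realized by two independent projections
    # (p = 0.3 and p = 0.1, both -0.72 pA).  The combined strength breaks
    # the otherwise exact cancellation between the feedforward excitation
    # a candidate population receives from the active one and the
    # feedback inhibition that same activity recruits through PV1; with
    # the weaker single projection no successor can ever ignite.
    p_pv1_pv1: float = 0.3
    w_pv1_pv1: float = -0.72
    p_pv1_pv1_b: float = 0.1
    w_pv1_pv1_b: float = -0.72
    p_pyr_pyr_next: float = 0.2
    w_pyr_pyr_next: float = 0.12
    delay_pyr_pyr_next: float = 10.0
    p_pyr_pv1: float = 0.2
    w_pyr_pv1: float = 0.12
    p_pv1_pyr: float = 0.2
    w_pv1_pyr: float = -1.08
    p_pv1_sst: float = 0.3
    w_pv1_sst: float = -0.6
    p_pv2_sst: float = 1.0
    w_pv2_sst: float = -6.0
    p_sst_pyr: float = 1.0
    w_sst_pyr: float = -4.8
    p_sst_pv1: float = 0.3
    w_sst_pv1: float = -0.6

    # external drive (rates Hz, weights pA)
    bg_rate_pyr: float = 2800.0
    bg_rate_pv1: float = 4500.0
    bg_rate_pv2: float = 0.0  # PV2 receives no background drive
    bg_rate_sst: float = 3200.0
    stim_rate_pyr: float = 2000.0
    stim_rate_pv1: float = 2000.0
    stim_rate_pv2: float = 2000.0
    w_drive_pyr: float = 0.12
    w_drive_pv1: float = 0.12
    w_drive_pv2: float = 0.36
    w_drive_sst: float = 0.12

    tau_rec: float = TAU_REC_DISCRETE
    weight_sd_frac: float = 0.1
    #: Absolute refractory period (ms) of every neuron.  Not a printed
    #: constant; it sets the handoff cadence of the winner-take-all
    #: sequence (larger values slow the within-epoch progression).
    t_ref_abs: float = 3.25
    #: Membrane floor (mV) of the SST cells only.  SST cells are crushed
    #: far below rest by PV2 while evidence is present; bounding their
    #: hyperpolarization lets the lateral-inhibition lock engage within a
    #: few ms of a gap onset, before the sequence can advance one more
    #: step.  Pyr and PV membranes are unbounded.
    sst_v_min: float = -30.0

    def __post_init__(self) -> None:
        for name in vars(self):
            if name.startswith("p_"):
                p = getattr(self, name)
                if not 0.0 <= p <= 1.0:
                    raise InvalidArgumentError(f"{name}={p} outside [0, 1]")

    @property
    def n_pyr_total(self) -> int:
        return self.n_populations * self.pyr_per_pop

    def pyr_pop(self, i: int) -> str:
        """1-based population label."""
        return f"Pyr{i:02d}"


@dataclass(frozen=True)
class StimulusProtocol:
    """Onset plus sustained stimulation epochs (ms).

    The onset drive targets population 1 during the first ``onset_ms`` of
    the first sustained epoch; by default the second epoch carries no
    onset drive.
    """

    epochs: tuple[tuple[float, float], ...] = ((100.0, 300.0), (800.0, 1000.0))
    onset_rate: float = 1000.0
    onset_ms: float = 100.0
    #: Every stimulus presentation carries its own transient onset to
    #: population 1; while a sequence is running, PV1 feedback inhibition
    #: vetoes the re-ignition of population 1 (removing that feedback is
    #: exactly the ``no_pv1_feedback`` control).
    onset_at_second_epoch: bool = True

    def __post_init__(self) -> None:
        eps = sorted(self.epochs)
        if tuple(eps) != tuple(self.epochs):
            raise InvalidArgumentError("epochs must be sorted")
        for (a0, b0), (a1, _) in zip(eps, eps[1:]):
            if b0 > a1:
                raise InvalidArgumentError("epochs must be non-overlapping")
        for a, b in eps:
            if a >= b:
                raise InvalidArgumentError("epoch start must precede stop")


def build_discrete(
    config: DiscreteConfig, seed: int, variant: str = "default"
) -> NetworkGraph:
    """Realize the discrete integrator as a network graph.

    ``variant="static_synapses"`` replaces the depressing within-population
    Pyr synapses by static ones of the same weight;
    ``variant="no_pv1_feedback"`` removes the Pyr -> PV1 projections, i.e.
    the feedback limb of the PV1 loop (PV1 keeps its feedforward stimulus
    and background drive).
    """
    if variant not in VARIANTS:
        raise InvalidArgumentError(f"unknown variant {variant!r}")
    c = config
    neuron = NeuronParams(t_ref_abs=c.t_ref_abs, V_min=-np.inf)
    net = NetworkGraph()
    for i in range(1, c.n_populations + 1):
        net.add_population(c.pyr_pop(i), c.pyr_per_pop, neuron)
    net.add_population(
        "SST",
        c.n_populations * c.sst_per_pop,
        replace(neuron, V_min=c.sst_v_min),
    )
    net.add_population("PV1", c.pv_count, neuron)
    net.add_population("PV2", c.pv_count, neuron)

    dep_kind = "static" if variant == "static_synapses" else "depressing"
    dep_spec = SynapseSpec(
        weight=c.w_pyr_pyr_within,
        delay=DELAY_DEFAULT,
        kind=dep_kind,
        U=U_DEPRESSION,
        tau_rec=c.tau_rec if dep_kind == "depressing" else None,
    )

    def _connect(name, pre, post, p, w, spec, post_sel=None, no_autapse=False):
        rng = rng_for(seed, f"conn:{name}")
        n_pre = net.populations[pre].size
        n_post = len(post_sel) if post_sel is not None else net.populations[post].size
        pi, pj = bernoulli_pairs(rng, n_pre, n_post, p, no_autapse=no_autapse)
        if post_sel is not None:
            pj = np.asarray(post_sel)[pj]
        w_real = jittered_weights(rng, w, len(pi), c.weight_sd_frac)
        net.connect(name, pre, post, pi, pj, w_real, spec)

    static = lambda w, delay=DELAY_DEFAULT: SynapseSpec(weight=w, delay=delay)

    for i in range(1, c.n_populations + 1):
        pyr_i = c.pyr_pop(i)
        nxt = c.pyr_pop(i % c.n_populations + 1)
        sst_block = np.arange((i - 1) * c.sst_per_pop, i * c.sst_per_pop)
        _connect(
            f"{pyr_i}->{pyr_i}", pyr_i, pyr_i, c.p_pyr_pyr_within,
            c.w_pyr_pyr_within, dep_spec, no_autapse=True,
        )
        _connect(
            f"{pyr_i}->SST(own)", pyr_i, "SST", c.p_pyr_sst_within,
            c.w_pyr_sst_within, static(c.w_pyr_sst_within), post_sel=sst_block,
        )
        _connect(
            f"{pyr_i}->{nxt}", pyr_i, nxt, c.p_pyr_pyr_next,
            c.w_pyr_pyr_next, static(c.w_pyr_pyr_next, c.delay_pyr_pyr_next),
        )
        if variant != "no_pv1_feedback":
            _connect(
                f"{pyr_i}->PV1", pyr_i, "PV1", c.p_pyr_pv1,
                c.w_pyr_pv1, static(c.w_pyr_pv1),
            )
        _connect(
            f"PV1->{pyr_i}", "PV1", pyr_i, c.p_pv1_pyr,
            c.w_pv1_pyr, static(c.w_pv1_pyr),
        )
        # SST cells of every *other* population laterally inhibit this one
        other_sst = np.concatenate(
            [
                np.arange((j - 1) * c.sst_per_pop, j * c.sst_per_pop)
                for j in range(1, c.n_populations + 1)
                if j != i
            ]
        )
        rng = rng_for(seed, f"conn:SST->{pyr_i}")
        if c.p_sst_pyr == 1.0:
            pi = np.repeat(other_sst, c.pyr_per_pop)
            pj = np.tile(np.arange(c.pyr_per_pop), len(other_sst))
        else:
            pi_loc, pj = bernoulli_pairs(rng, len(other_sst), c.pyr_per_pop, c.p_sst_pyr)
            pi = other_sst[pi_loc]
        w_real = jittered_weights(rng, c.w_sst_pyr, len(pi), c.weight_sd_frac)
        net.connect(f"SST->{pyr_i}", "SST", pyr_i, pi, pj, w_real, static(c.w_sst_pyr))

    _connect("PV1->PV1", "PV1", "PV1", c.p_pv1_pv1, c.w_pv1_pv1,
             static(c.w_pv1_pv1), no_autapse=True)
    _connect("PV1->PV1b", "PV1", "PV1", c.p_pv1_pv1_b, c.w_pv1_pv1_b,
             static(c.w_pv1_pv1_b), no_autapse=True)
    _connect("PV1->SST", "PV1", "SST", c.p_pv1_sst, c.w_pv1_sst, static(c.w_pv1_sst))
    _connect("PV2->SST", "PV2", "SST", c.p_pv2_sst, c.w_pv2_sst, static(c.w_pv2_sst))
    _connect("SST->PV1", "SST", "PV1", c.p_sst_pv1, c.w_sst_pv1, static(c.w_sst_pv1))
    return net


def make_discrete_drive(
    config: DiscreteConfig,
    protocol: StimulusProtocol,
    duration: float,
    net: NetworkGraph,
) -> DriveSchedule:
    c = config
    d = DriveSchedule()
    all_pyr = np.concatenate(
        [net.populations[c.pyr_pop(i)].gids for i in range(1, c.n_populations + 1)]
    )
    pv1 = net.populations["PV1"].gids
    pv2 = net.populations["PV2"].gids
    sst = net.populations["SST"].gids
    if c.bg_rate_pyr > 0:
        d.add_poisson(all_pyr, c.bg_rate_pyr, c.w_drive_pyr, 0.0, duration, "bg:Pyr")
    if c.bg_rate_pv1 > 0:
        d.add_poisson(pv1, c.bg_rate_pv1, c.w_drive_pv1, 0.0, duration, "bg:PV1")
    if c.bg_rate_pv2 > 0:
        d.add_poisson(pv2, c.bg_rate_pv2, c.w_drive_pv2, 0.0, duration, "bg:PV2")
    if c.bg_rate_sst > 0:
        d.add_poisson(sst, c.bg_rate_sst, c.w_drive_sst, 0.0, duration, "bg:SST")
    for k, (a, b) in enumerate(protocol.epochs):
        d.add_poisson(all_pyr, c.stim_rate_pyr, c.w_drive_pyr, a, b, f"stim:Pyr:{k}")
        d.add_poisson(pv1, c.stim_rate_pv1, c.w_drive_pv1, a, b, f"stim:PV1:{k}")
        d.add_poisson(pv2, c.stim_rate_pv2, c.w_drive_pv2, a, b, f"stim:PV2:{k}")
        if k == 0 or protocol.onset_at_second_epoch:
            d.add_poisson(
                net.populations[c.pyr_pop(1)].gids,
                protocol.onset_rate,
                c.w_drive_pyr,
                a,
                a + protocol.onset_ms,
                f"onset:{k}",
            )
    return d


# ---------------------------------------------------------------------------
# Experiment driver and population-level summaries
# ---------------------------------------------------------------------------

def population_rate_table(
    raster, config: DiscreteConfig, bin_ms: float = 50.0
) -> pd.DataFrame:
    """Population-mean Pyr rates (Hz/neuron) in non-overlapping bins.

    Rows: bin start times; columns: 1-based population index.
    """
    edges = np.arange(0.0, raster.duration + bin_ms / 2, bin_ms)
    out = {}
    for i in range(1, config.n_populations + 1):
        _, t = raster.select(config.pyr_pop(i))
        counts, _ = np.histogram(t, bins=edges)
        out[i] = counts / (config.pyr_per_pop * bin_ms / 1000.0)
    return pd.DataFrame(out, index=edges[:-1])


def activated_populations(
    rates: pd.DataFrame, threshold_hz: float = 5.0
) -> list[int]:
    """1-based indices of populations whose mean rate exceeds the
    activation threshold in at least one bin."""
    return [int(i) for i in rates.columns if (rates[i] > threshold_hz).any()]


def gap_holding_population(
    rates: pd.DataFrame,
    gap: tuple[float, float] = (300.0, 800.0),
    threshold_hz: float = 5.0,
    min_fraction: float = 0.9,
) -> int | None:
    """The unique population persistently active through the gap, if any.

    A population qualifies when its rate exceeds the threshold in at least
    ``min_fraction`` of the gap bins; returns ``None`` when no or several
    populations qualify.
    """
    sel = rates[(rates.index >= gap[0]) & (rates.index < gap[1])]
    frac = (sel > threshold_hz).mean(axis=0)
    holders = [int(i) for i in rates.columns if frac[i] >= min_fraction]
    return holders[0] if len(holders) == 1 else None


def first_activation_times(
    rates: pd.DataFrame, threshold_hz: float = 5.0
) -> dict[int, float]:
    """Time of the first supra-threshold bin per activated population."""
    out = {}
    for i in rates.columns:
        hits = rates.index[rates[i] > threshold_hz]
        if len(hits):
            out[int(i)] = float(hits[0])
    return out


def resumption_population(
    rates: pd.DataFrame,
    second_epoch: tuple[float, float] = (800.0, 1000.0),
    gap: tuple[float, float] = (300.0, 800.0),
    threshold_hz: float = 5.0,
) -> int | None:
    """First population newly activated after the gap ends."""
    holder = gap_holding_population(rates, gap, threshold_hz)
    sel = rates[(rates.index >= second_epoch[0]) & (rates.index < second_epoch[1])]
    first = first_activation_times(sel, threshold_hz)
    candidates = {i: t for i, t in first.items() if i != holder}
    if not candidates:
        return None
    return min(candidates, key=candidates.get)


def run_discrete_experiment(
    config: DiscreteConfig,
    protocol: StimulusProtocol,
    duration: float,
    seed: int,
    variant: str = "default",
    dt: float = 0.1,
):
    """Build, drive and simulate the discrete integrator.

    Returns ``(raster, rate_table)`` where the rate table holds 50-ms
    binned population-mean Pyr rates.
    """
    if duration < max(b for _, b in protocol.epochs):
        raise InvalidArgumentError("duration must cover the last stimulus epoch")
    net = build_discrete(config, seed, variant)
    drive = make_discrete_drive(config, protocol, duration, net)
    raster = run_network(net, drive, duration, dt=dt, seed=seed)
    return raster, population_rate_table(raster, config)
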