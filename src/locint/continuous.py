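"""Continuous location-code integrator: a 4,000-coordinate ring attractor.

Pyramidal, SST1 and SST2 cells share a circular lattice of 4,000 unique
coordinates; PV1/PV2 are unstructured pools.  Neighboring Pyr cells
(circular distance <= 200) excite each other through depressing synapses,
so an activity bump self-propagates clockwise while sensory drive is on.
SST2 mirrors the bump one-to-one and inhibits the coordinates *behind* it
(offsets 400..800 counterclockwise), vetoing backward propagation.  During
a temporal gap the stimulus-driven PV2 pool falls silent, releasing SST1,
which is driven one-to-one by the bump and inhibits every Pyr cell except
the bump's own neighborhood - freezing the bump in place (lossless
retention).  The sustained-input rate follows
``I_sustained = 400 + 100 * alpha`` (Hz) for the PV pools and four times
that for Pyr, so ``alpha`` is the strength of the sensory evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drive import DriveSchedule
from .engine import run_network
from .network import (
    NetworkGraph,
    fixed_indegree_pairs,
    jittered_weights,
    rng_for,
)
from .params import (
    DELAY_DEFAULT,
    TAU_REC_CONTINUOUS,
    U_DEPRESSION,
    InvalidArgumentError,
    NeuronParams,
    SynapseSpec,
)


@dataclass(frozen=True)
class ContinuousConfig:
    """Structural and drive parameters of the ring integrator."""

    lattice_size: int = 4000
    pyr_neighbor_halfwidth: int = 200
    pv1_count: int = 1000
    pv2_count: int = 1000

    # in-degree table: (number of presynaptic partners, mean weight pA).
    # For the depressing Pyr->Pyr synapses the strength is the PSC
    # amplitude of a fully recovered synapse, so the absolute efficacy
    # passed to the depression model is w_pyr_pyr / U.
    k_pyr_pyr: int = 400  # realized by the +-200 neighborhood rule
    w_pyr_pyr: float = 0.52
    k_pyr_pv1: int = 400
    w_pyr_pv1: float = 0.52
    w_pyr_sst: float = 11.7  # one-to-one topographic drive
    k_pv1_pyr: int = 160
    w_pv1_pyr: float = -1.87
    k_pv1_pv1: int = 160
    w_pv1_pv1: float = -0.78
    k_pv1_sst1: int = 150
    w_pv1_sst1: float = -0.78
    k_pv2_sst1: int = 1000
    w_pv2_sst1: float = -0.78
    k_sst1_pyr: int = 3600  # coordinate rule: offsets 200..3799
    w_sst1_pyr: float = -0.78
    k_sst1_pv1: int = 1200
    w_sst1_pv1: float = -0.78
    k_sst2_pyr: int = 400  # coordinate rule: offsets -400..-799
    w_sst2_pyr: float = -0.78
    sst2_offset_lo: int = 400
    sst2_offset_hi: int = 800  # exclusive; 400 offsets in total

    # external drive (Hz); every external synapse weighs 0.13 pA
    bg_rate_pyr: float = 3850.0
    bg_rate_pv1: float = 3850.0
    bg_rate_pv2: float = 3000.0
    bg_rate_sst1: float = 2000.0
    bg_rate_sst2: float = 2000.0
    w_drive: float = 0.13

    tau_rec: float = TAU_REC_CONTINUOUS
    weight_sd_frac: float = 0.1
    #: quenched per-neuron background-rate heterogeneity (CV) of the Pyr
    #: background.  Identical cells parked exactly at rheobase by a
    #: uniform background discharge in lattice-wide synchronous volleys;
    #: a spread of Pyr operating points keeps the bump asynchronous.  The
    #: PV pools stay homogeneous so that they fall silent together during
    #: a gap, which is what releases the SST1 retention circuit.
    bg_rate_sd_frac: float = 0.2
    t_ref_abs: float = 2.0
    sst_v_min: float = -30.0  # membrane floor of the SST pools

    def neuron_params(self, pop: str) -> NeuronParams:
        v_min = self.sst_v_min if pop.startswith("SST") else -np.inf
        return NeuronParams(t_ref_abs=self.t_ref_abs, V_min=v_min)


@dataclass(frozen=True)
class StimulusSpec:
    """Sensory input protocol for the ring integrator.

    ``alpha`` scales the sustained drive (see :func:`sustained_rate`); the
    onset burst targets the ``onset_n`` lowest-coordinate Pyr cells during
    ``onset_window`` so the bump always forms at the same place.
    """

    alpha: float = 8.0
    epochs: tuple[tuple[float, float], ...] = ((100.0, 1000.0),)
    onset_n: int = 100
    #: The onset burst leads the sustained epochs by 50 ms and is strong
    #: enough (+16 mV mean depolarization) that the seeded zone ignites
    #: before the rest of the lattice finishes its charge-up transient;
    #: this pins bump formation to the lowest coordinates on every seed.
    onset_rate: float = 3000.0
    onset_window: tuple[float, float] = (50.0, 200.0)
    #: Lowest coordinate of the seeded zone.  Ignition recruits the seed's
    #: neighbors on both sides before the backward-veto (SST2) engages, so
    #: the seed sits one neighborhood-width past coordinate 0 to keep the
    #: nascent bump from smearing across the periodic wrap point.
    onset_origin: int = 400

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be non-negative")
        eps = sorted(self.epochs)
        for (a0, b0), (a1, _) in zip(eps, eps[1:]):
            if b0 > a1:
                raise InvalidArgumentError("epochs must be non-overlapping")


GAP_EPOCHS = ((100.0, 300.0), (800.0, 1000.0))


def sustained_rate(alpha: float, target_group: str) -> float:
    """Sustained stimulus rate (Hz): ``400 + 100 alpha`` for the PV pools,
    four times that for Pyr."""
    if alpha < 0:
        raise InvalidArgumentError("alpha must be non-negative")
    if target_group not in ("pv", "pyr"):
        raise InvalidArgumentError(f"unknown target group {target_group!r}")
    base = 400.0 + 100.0 * alpha
    return 4.0 * base if target_group == "pyr" else base


def _circ_offsets(coords: np.ndarray, offsets: np.ndarray, L: int):
    """(pre, post) pairs connecting every coordinate to coordinate+offset."""
    pre = np.repeat(coords, len(offsets))
    post = (pre + np.tile(offsets, len(coords))) % L
    return pre, post


def build_continuous(config: ContinuousConfig, seed: int) -> NetworkGraph:
    """Realize the ring integrator as a network graph.

    Coordinate rules (0-based internally, periodic mod ``lattice_size``):

    * Pyr <-> Pyr: mutual depressing links for circular distance <= 200.
    * Pyr -> SST1/SST2: one-to-one at equal coordinate (11.7 pA, enough
      for a single Pyr spike to fire the target on top of its background
      depolarization).
    * SST1 -> Pyr: offsets +200..+3799 (everything except the 399-cell
      bump neighborhood), in-degree exactly 3,600.
    * SST2 -> Pyr: offsets -400..-799 (the 400 coordinates behind), i.e.
      in-degree exactly 400.
    * Remaining projections draw fixed in-degrees at random.
    """
    c = config
    L = c.lattice_size
    if c.k_pyr_pv1 > L or c.k_sst1_pv1 > L:
        raise InvalidArgumentError("in-degree exceeds source population size")
    net = NetworkGraph()
    coords = np.arange(L)
    net.add_population("Pyr", L, c.neuron_params("Pyr"), coords=coords)
    net.add_population("PV1", c.pv1_count, c.neuron_params("PV1"))
    net.add_population("PV2", c.pv2_count, c.neuron_params("PV2"))
    net.add_population("SST1", L, c.neuron_params("SST1"), coords=coords)
    net.add_population("SST2", L, c.neuron_params("SST2"), coords=coords)

    def _w(label, mean, n):
        return jittered_weights(rng_for(seed, f"conn:{label}"), mean, n, c.weight_sd_frac)

    static = lambda w: SynapseSpec(weight=w, delay=DELAY_DEFAULT)

    # Pyr <-> Pyr neighborhood, depressing
    hw = c.pyr_neighbor_halfwidth
    offs = np.concatenate([np.arange(-hw, 0), np.arange(1, hw + 1)])
    pre, post = _circ_offsets(coords, offs, L)
    a_pyr = c.w_pyr_pyr / U_DEPRESSION  # absolute efficacy: first spike = printed pA
    dep = SynapseSpec(
        weight=a_pyr, delay=DELAY_DEFAULT, kind="depressing",
        U=U_DEPRESSION, tau_rec=c.tau_rec,
    )
    net.connect("Pyr->Pyr", "Pyr", "Pyr", pre, post,
                _w("Pyr->Pyr", a_pyr, len(pre)), dep)

    # one-to-one topographic drive of both SST pools
    net.connect("Pyr->SST1", "Pyr", "SST1", coords, coords,
                _w("Pyr->SST1", c.w_pyr_sst, L), static(c.w_pyr_sst))
    net.connect("Pyr->SST2", "Pyr", "SST2", coords, coords,
                _w("Pyr->SST2", c.w_pyr_sst, L), static(c.w_pyr_sst))

    # SST1 -> Pyr: all offsets except the bump neighborhood (exactly 3,600)
    offs1 = np.arange(hw, hw + c.k_sst1_pyr)
    pre, post = _circ_offsets(coords, offs1, L)
    net.connect("SST1->Pyr", "SST1", "Pyr", pre, post,
                _w("SST1->Pyr", c.w_sst1_pyr, len(pre)), static(c.w_sst1_pyr))

    # SST2 -> Pyr: the coordinates behind (counterclockwise), exactly 400
    offs2 = -np.arange(c.sst2_offset_lo, c.sst2_offset_hi)
    pre, post = _circ_offsets(coords, offs2, L)
    net.connect("SST2->Pyr", "SST2", "Pyr", pre, post,
                _w("SST2->Pyr", c.w_sst2_pyr, len(pre)), static(c.w_sst2_pyr))

    # random fixed-in-degree projections
    def _fixed(label, pre_pop, post_pop, k, mean, no_autapse=False):
        rng = rng_for(seed, f"conn:{label}")
        n_pre = net.populations[pre_pop].size
        n_post = net.populations[post_pop].size
        pi, pj = fixed_indegree_pairs(rng, n_pre, n_post, k, no_autapse=no_autapse)
        net.connect(label, pre_pop, post_pop, pi, pj,
                    _w(label, mean, len(pi)), static(mean))

    _fixed("Pyr->PV1", "Pyr", "PV1", c.k_pyr_pv1, c.w_pyr_pv1)
    _fixed("PV1->Pyr", "PV1", "Pyr", c.k_pv1_pyr, c.w_pv1_pyr)
    _fixed("PV1->PV1", "PV1", "PV1", c.k_pv1_pv1, c.w_pv1_pv1, no_autapse=True)
    _fixed("PV1->SST1", "PV1", "SST1", c.k_pv1_sst1, c.w_pv1_sst1)
    _fixed("PV2->SST1", "PV2", "SST1", c.k_pv2_sst1, c.w_pv2_sst1)
    _fixed("SST1->PV1", "SST1", "PV1", c.k_sst1_pv1, c.w_sst1_pv1)
    return net


def make_continuous_drive(
    config: ContinuousConfig,
    stim: StimulusSpec,
    duration: float,
    net: NetworkGraph,
) -> DriveSchedule:
    """Background plus stimulus drive for one ring-integrator run.

    The background switches on together with the first stimulus epoch.
    The Pyr background alone depolarizes cells exactly to rheobase, so a
    background-only pre-stimulus period would drift into spontaneous,
    randomly placed bump nucleation; starting it with the stimulus keeps
    the pre-stimulus window silent and lets the onset input decide where
    the bump forms.
    """
    c = config
    d = DriveSchedule()
    pyr = net.populations["Pyr"].gids
    bg_start = min(min(a for a, _ in stim.epochs), stim.onset_window[0])
    for pop, rate in [
        ("Pyr", c.bg_rate_pyr),
        ("PV1", c.bg_rate_pv1),
        ("PV2", c.bg_rate_pv2),
        ("SST1", c.bg_rate_sst1),
        ("SST2", c.bg_rate_sst2),
    ]:
        if rate > 0:
            d.add_poisson(net.populations[pop].gids, rate, c.w_drive, bg_start,
                          duration, f"bg:{pop}", rate_sd_frac=c.bg_rate_sd_frac)
    r_pyr = sustained_rate(stim.alpha, "pyr")
    r_pv = sustained_rate(stim.alpha, "pv")
    for k, (a, b) in enumerate(stim.epochs):
        d.add_poisson(pyr, r_pyr, c.w_drive, a, b, f"stim:Pyr:{k}")
        d.add_poisson(net.populations["PV1"].gids, r_pv, c.w_drive, a, b, f"stim:PV1:{k}")
        d.add_poisson(net.populations["PV2"].gids, r_pv, c.w_drive, a, b, f"stim:PV2:{k}")
    a0, b0 = stim.onset_window
    lo = stim.onset_origin
    d.add_poisson(pyr[lo : lo + stim.onset_n], stim.onset_rate, c.w_drive, a0, b0, "onset")
    return d


def run_continuous_experiment(
    config: ContinuousConfig,
    stim: StimulusSpec,
    duration: float,
    seed: int,
    dt: float = 0.1,
):
    """Build, drive and simulate the ring integrator; returns the raster."""
    if duration < max(b for _, b in stim.epochs):
        raise InvalidArgumentError("duration must cover the last stimulus epoch")
    net = build_continuous(config, seed)
    drive = make_continuous_drive(config, stim, duration, net)
    return run_network(net, drive, duration, dt=dt, seed=seed)


def travel_time_sweep(
    config: ContinuousConfig,
    alphas,
    seeds,
    duration: float = 1000.0,
    epochs=((100.0, 1000.0),),
):
    """Bump travel time versus sensory-input strength.

    Runs one independently built and driven model per (alpha, seed) and
    applies the travel-time statistic (first 10-ms bin in which the spike
    count of the 400 highest-coordinate Pyr cells exceeds the mean + 2 SD
    of all bins, relative to stimulus onset).  Returns a tidy DataFrame
    with per-run times and per-alpha mean/SD; runs without a threshold
    crossing are recorded as missing.
    """
    import pandas as pd

    from .analysis import travel_time

    alphas = list(alphas)
    if len(alphas) < 2:
        raise InvalidArgumentError("need at least two alpha values")
    onset = epochs[0][0]
    rows = []
    for alpha in alphas:
        for seed in seeds:
            stim = StimulusSpec(alpha=alpha, epochs=tuple(epochs))
            raster = run_continuous_experiment(config, stim, duration, seed)
            # skip the charge-up transient of the fresh network when
            # searching for the arrival surge
            tt = travel_time(raster, stimulus_onset_ms=onset, scan_from_ms=onset + 300.0)
            rows.append({"alpha": alpha, "seed": seed, "travel_time_ms": tt})
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("alpha")["travel_time_ms"].agg(["mean", "std", "count"]).reset_index()
    )
    return df, summary
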