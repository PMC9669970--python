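"""Current-based LIF network engine.

The membrane/PSC system of every neuron is linear between spikes::

    C dV/dt = -C (V - E_L)/tau_m + I_syn(t) + I_dc
    dI_syn/dt = -I_syn/tau_syn

and is advanced with the exact exponential propagator of this 2x2 system,
so subthreshold dynamics are exact at the grid points for any dt
(unconditionally stable).  A presynaptic spike adds its (possibly
depressed) PSC amplitude to ``I_syn`` of each target at spike time plus
the conduction delay; thresholds are checked at step boundaries, spikes
are recorded at the end of the step in which the crossing occurred, and
the membrane is clamped at ``V_reset`` for the absolute refractory period.

Depressing synapses follow the depression-only Tsodyks-Markram rule.  The
available resource ``x`` recovers exponentially between presynaptic spikes
and a fraction ``U`` of it is released per spike; because recovery depends
only on the presynaptic spike train, one state per (group, presynaptic
neuron) suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .drive import DriveSchedule
from .network import ConnectionGroup, NetworkGraph, rng_for
from .params import InvalidArgumentError, NeuronParams, SynapseSpec
from .raster import SpikeRaster


class EngineError(RuntimeError):
    """Numerical failure inside the simulation loop (non-finite state)."""


# ---------------------------------------------------------------------------
# Tsodyks-Markram depression
# ---------------------------------------------------------------------------

@dataclass
class TMState:
    """Available synaptic resource of one depressing connection (or of all
    connections sharing a presynaptic neuron, which evolve identically)."""

    x: float = 1.0  # post-release resource after the previous spike


def tm_release(state: TMState, spec: SynapseSpec, dt_since_last: float) -> tuple[float, TMState]:
    """Amplitude transmitted by a presynaptic spike and the updated state.

    The resource recovers as ``x' = 1 - (1 - x) * exp(-dt/tau_rec)``; the
    spike releases ``weight * U * x'`` and leaves ``x' * (1 - U)`` behind.
    ``dt_since_last`` may be ``inf`` for the first spike (full resource).
    """
    if spec.kind != "depressing":
        raise InvalidArgumentError("tm_release requires a depressing synapse")
    xr = 1.0 - (1.0 - state.x) * math.exp(-dt_since_last / spec.tau_rec)
    return spec.weight * spec.U * xr, TMState(x=xr * (1.0 - spec.U))


# ---------------------------------------------------------------------------
# Single-neuron reference stepper
# ---------------------------------------------------------------------------

def _propagators(p: NeuronParams, tau_syn: float, dt: float):
    pm = math.exp(-dt / p.tau_m)
    ps = math.exp(-dt / tau_syn)
    if abs(p.tau_m - tau_syn) < 1e-12:
        raise InvalidArgumentError("tau_m == tau_syn is not supported")
    pms = (tau_syn * p.tau_m / (p.tau_m - tau_syn)) / p.C * (pm - ps)
    pdc = p.tau_m / p.C * (1.0 - pm)
    return pm, ps, pms, pdc


def lif_response(
    params: NeuronParams,
    syn: SynapseSpec,
    input_spike_times,
    duration: float,
    dt: float,
    I_const: float = 0.0,
    psp_mode: str = "exp_psc",
):
    """Response of a single LIF neuron to a fixed presynaptic spike train.

    Each presynaptic spike is delivered after ``syn.delay``; depressing
    synapses are depressed along the train.  Serves both as a user-facing
    utility and as the independent single-neuron oracle the network engine
    is tested against.

    Returns ``(t, V, spike_times)`` with ``t``/``V`` sampled at the grid
    points ``0, dt, ..., duration``.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    pm, ps, pms, pdc = _propagators(params, syn.tau_syn, dt)
    ref_steps = int(round(params.t_ref_abs / dt))

    # realized arrival amplitudes on the step grid
    arrivals: dict[int, float] = {}
    state = TMState()
    last = -math.inf
    for t_sp in sorted(np.atleast_1d(np.asarray(input_spike_times, dtype=float))):
        if syn.kind == "depressing":
            amp, state = tm_release(state, syn, t_sp - last)
            last = t_sp
        else:
            amp = syn.weight
        step = int(round((t_sp + syn.delay) / dt))
        arrivals[step] = arrivals.get(step, 0.0) + amp

    V = np.empty(n_steps + 1)
    V[0] = params.E_L
    v, i_syn, refr = params.E_L, 0.0, 0
    out_spikes = []
    for s in range(n_steps):
        a = arrivals.get(s, 0.0)
        if psp_mode == "exp_psc":
            i_syn += a
        elif psp_mode == "delta":
            if refr == 0:
                v += a * syn.tau_syn / params.C
        else:
            raise InvalidArgumentError(f"unknown psp_mode {psp_mode!r}")
        if refr > 0:
            v = params.V_reset
            refr -= 1
        else:
            v = params.E_L + (v - params.E_L) * pm + i_syn * pms + I_const * pdc
            if v < params.V_min:
                v = params.V_min
        i_syn *= ps
        if refr == 0 and v >= params.V_th:
            out_spikes.append((s + 1) * dt)
            v = params.V_reset
            refr = ref_steps
        V[s + 1] = v
    return np.arange(n_steps + 1) * dt, V, np.array(out_spikes)


def psp_peak(params: NeuronParams, weight: float, tau_syn: float) -> tuple[float, float]:
    """Closed-form peak (time, amplitude) of a single exponential-PSC PSP.

    For a PSC jump ``w`` at t=0 the membrane deflection is
    ``(w tau_m tau_syn / (C (tau_m - tau_syn))) (exp(-t/tau_m) - exp(-t/tau_syn))``
    peaking at ``t* = ln(tau_m/tau_syn) tau_m tau_syn / (tau_m - tau_syn)``.
    """
    tm, ts, C = params.tau_m, tau_syn, params.C
    t_star = math.log(tm / ts) * tm * ts / (tm - ts)
    amp = weight * tm * ts / (C * (tm - ts)) * (math.exp(-t_star / tm) - math.exp(-t_star / ts))
    return t_star, amp


# ---------------------------------------------------------------------------
# Replayed (pre-recorded) spike sources
# ---------------------------------------------------------------------------

@dataclass
class ReplaySource:
    """Feedforward injection of a recorded spike train through static synapses.

    ``pre_ids``/``times`` are parallel event arrays over ``n_pre`` virtual
    source neurons; the CSR triple (``indptr``, ``post_gids``, ``weights``)
    maps each source onto network targets, as in
    :class:`locint.network.ConnectionGroup`.
    """

    n_pre: int
    pre_ids: np.ndarray
    times: np.ndarray
    indptr: np.ndarray
    post_gids: np.ndarray
    weights: np.ndarray
    delay: float = 1.5
    label: str = "replay"


# ---------------------------------------------------------------------------
# Network engine
# ---------------------------------------------------------------------------

def _delay_steps(delay: float, dt: float) -> int:
    k = delay / dt
    if delay < dt - 1e-9 or abs(k - round(k)) > 1e-6:
        raise InvalidArgumentError(
            f"delay {delay} ms must be a positive integer multiple of dt={dt} ms"
        )
    return int(round(k))


def run_network(
    net: NetworkGraph,
    drive: DriveSchedule | None,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    replay: tuple[ReplaySource, ...] | list = (),
    record_v: tuple[int, ...] = (),
    psp_mode: str = "exp_psc",
    init_v: str = "resting",
) -> SpikeRaster:
    """Simulate a network and return its spike raster.

    Deterministic given ``(net, drive, seed, dt)``: every stochastic input
    draws from a stream labeled by its drive entry, derived from the master
    seed.  Raises :class:`EngineError` if the state becomes non-finite.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    if psp_mode not in ("exp_psc", "delta"):
        raise InvalidArgumentError(f"unknown psp_mode {psp_mode!r}")
    drive = drive or DriveSchedule()
    n = net.n_neurons
    n_steps = int(round(duration / dt))

    # ---- per-neuron constants -------------------------------------------
    pops = list(net.populations.values())
    tau_syn = None
    for g in net.groups:
        if tau_syn is None:
            tau_syn = g.spec.tau_syn
        elif abs(g.spec.tau_syn - tau_syn) > 1e-12:
            raise InvalidArgumentError("engine requires a single tau_syn per network")
    if tau_syn is None:
        tau_syn = 2.0

    pm = np.empty(n)
    pms = np.empty(n)
    pdc = np.empty(n)
    v_th = np.empty(n)
    v_res = np.empty(n)
    v_min = np.empty(n)
    e_l = np.empty(n)
    ref_steps = np.empty(n, dtype=np.int64)
    inv_c_ts = np.empty(n)
    for p in pops:
        a, b = p.start, p.stop
        _pm, _ps, _pms, _pdc = _propagators(p.params, tau_syn, dt)
        pm[a:b], pms[a:b], pdc[a:b] = _pm, _pms, _pdc
        v_th[a:b], v_res[a:b], e_l[a:b] = p.params.V_th, p.params.V_reset, p.params.E_L
        v_min[a:b] = p.params.V_min
        ref_steps[a:b] = int(round(p.params.t_ref_abs / dt))
        inv_c_ts[a:b] = tau_syn / p.params.C
    ps_decay = math.exp(-dt / tau_syn)

    # ---- compiled connection groups -------------------------------------
    g_delay = [_delay_steps(g.spec.delay, dt) for g in net.groups]
    g_x = [np.ones(net.populations[g.pre].size) for g in net.groups]
    g_tlast = [np.full(net.populations[g.pre].size, -np.inf) for g in net.groups]
    pop_starts = np.array([p.start for p in pops])
    groups_of_pop: list[list[int]] = [[] for _ in pops]
    pop_index = {p.name: i for i, p in enumerate(pops)}
    for gi, g in enumerate(net.groups):
        groups_of_pop[pop_index[g.pre]].append(gi)

    # ---- replay arrival buckets -----------------------------------------
    replay_buckets: dict[int, list[tuple[int, np.ndarray]]] = {}
    for ri, src in enumerate(replay):
        dsteps = _delay_steps(src.delay, dt)
        arrive = np.round(np.asarray(src.times) / dt).astype(np.int64) + dsteps
        order = np.argsort(arrive, kind="stable")
        arrive, pre = arrive[order], np.asarray(src.pre_ids)[order]
        for step in np.unique(arrive):
            if 0 <= step < n_steps:
                replay_buckets.setdefault(int(step), []).append((ri, pre[arrive == step]))

    # ---- drive ----------------------------------------------------------
    poisson = []
    for entry in drive.poisson:
        if len(entry.targets) and (entry.targets.min() < 0 or entry.targets.max() >= n):
            raise InvalidArgumentError(f"drive {entry.label!r} targets missing neurons")
        poisson.append(
            (
                int(round(entry.start / dt)),
                int(round(entry.stop / dt)),
                entry.target_rates(seed) * dt / 1000.0,
                entry.targets,
                entry.weight,
                rng_for(seed, f"poisson:{entry.label}"),
            )
        )
    dc_events: dict[int, list[tuple[np.ndarray, float]]] = {}
    for c in drive.currents:
        dc_events.setdefault(int(round(c.start / dt)), []).append((c.targets, c.amplitude))
        dc_events.setdefault(int(round(c.stop / dt)), []).append((c.targets, -c.amplitude))

    # ---- state ----------------------------------------------------------
    if init_v == "resting":
        V = e_l.copy()
    elif init_v == "uniform":
        # desynchronizes the start-up transient; common practice for
        # networks whose background drive parks cells near threshold.
        V = v_res + rng_for(seed, "init_v").random(n) * 0.25 * (v_th - v_res)
    elif init_v == "hyperpolarized":
        # start one threshold-depth below rest, uniformly spread.  With a
        # background depolarization at rheobase the population's first
        # threshold crossings then arrive only after ~tau_m ln(2 dV/noise)
        # ms and are maximally dispersed, keeping the pre-stimulus window
        # quiet so that the stimulus onset, not the start-up transient,
        # decides where the bump forms.
        V = e_l - rng_for(seed, "init_v").random(n) * (v_th - e_l)
    else:
        raise InvalidArgumentError(f"unknown init_v {init_v!r}")
    I = np.zeros(n)
    I_dc = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    L = max(g_delay, default=1) + 2
    ring: list[list[tuple[int, np.ndarray, np.ndarray]]] = [[] for _ in range(L)]
    spike_gids: list[np.ndarray] = []
    spike_times: list[np.ndarray] = []
    v_trace = {gid: np.empty(n_steps + 1) for gid in record_v}
    for gid in record_v:
        v_trace[gid][0] = V[gid]

    def _gather(entries) -> None:
        """Accumulate delayed synaptic arrivals into I (or V in delta mode)."""
        idx_parts, val_parts = [], []
        for gi, pres, factors in entries:
            g = net.groups[gi]
            iptr, posts, w = g.indptr, g.post_gids, g.weights
            for j, f in zip(pres, factors):
                s0, s1 = iptr[j], iptr[j + 1]
                if s0 == s1:
                    continue
                idx_parts.append(posts[s0:s1])
                val_parts.append(w[s0:s1] * f)
        if idx_parts:
            idx = np.concatenate(idx_parts)
            vals = np.concatenate(val_parts)
            if psp_mode == "exp_psc":
                I[:] += np.bincount(idx, weights=vals, minlength=n)
            else:
                V[:] += np.bincount(idx, weights=vals, minlength=n) * inv_c_ts

    for s in range(n_steps):
        slot = s % L
        if ring[slot]:
            _gather(ring[slot])
            ring[slot] = []
        if s in replay_buckets:
            for ri, pres in replay_buckets[s]:
                src = replay[ri]
                idx_parts, val_parts = [], []
                for j in pres:
                    s0, s1 = src.indptr[j], src.indptr[j + 1]
                    if s0 < s1:
                        idx_parts.append(src.post_gids[s0:s1])
                        val_parts.append(src.weights[s0:s1])
                if idx_parts:
                    inc = np.bincount(
                        np.concatenate(idx_parts),
                        weights=np.concatenate(val_parts),
                        minlength=n,
                    )
                    if psp_mode == "exp_psc":
                        I += inc
                    else:
                        V += inc * inv_c_ts
        for start, stop, lam, targets, w, rng in poisson:
            if start <= s < stop:
                counts = rng.poisson(lam)
                if psp_mode == "exp_psc":
                    I[targets] += counts * w
                else:
                    V[targets] += counts * w * inv_c_ts[targets]
        if s in dc_events:
            for targets, amp in dc_events[s]:
                I_dc[targets] += amp

        # exact propagation over (s*dt, (s+1)*dt]
        V = e_l + (V - e_l) * pm + I * pms + I_dc * pdc
        np.maximum(V, v_min, out=V)
        in_ref = refr > 0
        if in_ref.any():
            V[in_ref] = v_res[in_ref]
            refr[in_ref] -= 1
        I *= ps_decay

        sp = np.nonzero(V >= v_th)[0]
        if len(sp):
            t_spike = (s + 1) * dt
            spike_gids.append(sp.astype(np.int64))
            spike_times.append(np.full(len(sp), t_spike))
            V[sp] = v_res[sp]
            refr[sp] = ref_steps[sp]
            pop_of = np.searchsorted(pop_starts, sp, side="right") - 1
            for pi in np.unique(pop_of):
                local = sp[pop_of == pi] - pop_starts[pi]
                for gi in groups_of_pop[pi]:
                    g = net.groups[gi]
                    if g.spec.kind == "depressing":
                        dt_since = t_spike - g_tlast[gi][local]
                        xr = 1.0 - (1.0 - g_x[gi][local]) * np.exp(-dt_since / g.spec.tau_rec)
                        factors = g.spec.U * xr
                        g_x[gi][local] = xr * (1.0 - g.spec.U)
                        g_tlast[gi][local] = t_spike
                    else:
                        factors = np.ones(len(local))
                    ring[(s + 1 + g_delay[gi]) % L].append((gi, local, factors))

        for gid in record_v:
            v_trace[gid][s + 1] = V[gid]
        if s % 1000 == 999 and not np.isfinite(V).all():
            raise EngineError(f"non-finite membrane potential at t={(s + 1) * dt:.1f} ms")

    gids = np.concatenate(spike_gids) if spike_gids else np.empty(0, np.int64)
    times = np.concatenate(spike_times) if spike_times else np.empty(0)
    raster = SpikeRaster(
        gids=gids,
        times=times,
        duration=duration,
        dt=dt,
        pops={p.name: (p.start, p.size) for p in pops},
        coords={p.name: p.coords for p in pops if p.coords is not None},
    )
    raster.v_trace = {g: t for g, t in v_trace.items()}  # type: ignore[attr-defined]
    return raster
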