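"""Single-neuron oracles, depression algebra, Poisson drive and engine
invariants of the LIF network engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locint.drive import DriveSchedule, generate_poisson_drive
from locint.engine import (
    ReplaySource,
    TMState,
    lif_response,
    psp_peak,
    run_network,
    tm_release,
)
from locint.network import NetworkGraph
from locint.params import DEFAULT_NEURON, InvalidArgumentError, NeuronParams, SynapseSpec
from locint.raster import validate_raster


# ---------------------------------------------------------------------------
# lif_response closed-form oracles
# ---------------------------------------------------------------------------

def test_resting_state_without_input():
    t, V, spikes = lif_response(DEFAULT_NEURON, SynapseSpec(weight=1.0), [], 50.0, 0.1)
    assert np.all(V == DEFAULT_NEURON.E_L)
    assert len(spikes) == 0


def test_subthreshold_psp_matches_double_exponential():
    """Exact propagator reproduces the closed-form PSP at every grid point."""
    p = NeuronParams()
    syn = SynapseSpec(weight=11.7, delay=1.5)
    t, V, spikes = lif_response(p, syn, [10.0], 60.0, 0.1)
    assert len(spikes) == 0  # 18.1 mV peak stays below the 20 mV threshold
    tau_m, tau_s, C = p.tau_m, syn.tau_syn, p.C
    rel = t - (10.0 + syn.delay)
    ref = np.where(
        rel > 0,
        11.7 * tau_m * tau_s / (C * (tau_m - tau_s))
        * (np.exp(-rel / tau_m) - np.exp(-rel / tau_s)),
        0.0,
    )
    np.testing.assert_allclose(V, ref, atol=1e-9)
    t_star, amp = psp_peak(p, 11.7, 2.0)
    assert amp == pytest.approx(18.1, abs=0.05)
    k = int(np.argmax(V))
    assert V[k] == pytest.approx(amp, rel=1e-4)  # peak between grid points
    assert t[k] - 11.5 == pytest.approx(t_star, abs=0.1)


@pytest.mark.parametrize("I_const", [4.52, 8.0])
def test_isi_under_constant_current_matches_formula(I_const):
    """Periodic firing: ISI = t_ref + tau_m ln(A/(A - V_th)), A = I tau_m / C,
    up to the one-step quantization of threshold detection."""
    p = DEFAULT_NEURON
    dt = 0.05
    _, _, spikes = lif_response(p, SynapseSpec(weight=0.0), [], 400.0, dt, I_const=I_const)
    A = I_const * p.tau_m / p.C
    theory = p.t_ref_abs + p.tau_m * math.log(A / (A - p.V_th))
    isis = np.diff(spikes)
    assert len(isis) >= 5
    assert np.all(np.abs(isis - theory) <= dt + 1e-9)


def test_fine_dt_converges_to_formula():
    p = DEFAULT_NEURON
    I = 4.52
    A = I * p.tau_m / p.C
    theory = p.t_ref_abs + p.tau_m * math.log(A / (A - p.V_th))
    errs = []
    for dt in (0.1, 0.01):
        _, _, spikes = lif_response(p, SynapseSpec(weight=0.0), [], 200.0, dt, I_const=I)
        errs.append(abs(np.diff(spikes).mean() - theory))
    assert errs[1] < errs[0]
    assert errs[1] < 0.011


def test_invalid_arguments_rejected():
    with pytest.raises(InvalidArgumentError):
        lif_response(DEFAULT_NEURON, SynapseSpec(weight=1.0), [], -1.0, 0.1)
    with pytest.raises(InvalidArgumentError):
        lif_response(DEFAULT_NEURON, SynapseSpec(weight=1.0), [], 10.0, 0.0)
    with pytest.raises(InvalidArgumentError):
        NeuronParams(tau_m=-1.0)
    with pytest.raises(InvalidArgumentError):
        SynapseSpec(weight=1.0, kind="depressing", U=0.0, tau_rec=100.0)


# ---------------------------------------------------------------------------
# Tsodyks-Markram depression
# ---------------------------------------------------------------------------

DEP = SynapseSpec(weight=1.8, kind="depressing", U=0.2, tau_rec=200.0)


def test_tm_first_release_and_update():
    amp, state = tm_release(TMState(), DEP, math.inf)
    assert amp == pytest.approx(1.8 * 0.2)
    assert state.x == pytest.approx(0.8)


def test_tm_exponential_recovery():
    _, state = tm_release(TMState(), DEP, math.inf)
    amp, _ = tm_release(state, DEP, 200.0)  # one recovery time constant later
    xr = 1.0 - 0.2 * math.exp(-1.0)
    assert amp == pytest.approx(1.8 * 0.2 * xr)


def test_tm_full_recovery_limit():
    _, state = tm_release(TMState(), DEP, math.inf)
    amp, state2 = tm_release(state, DEP, 1e9)
    assert amp == pytest.approx(1.8 * 0.2)
    assert state2.x == pytest.approx(0.8)


def test_tm_rejects_static_synapse():
    with pytest.raises(InvalidArgumentError):
        tm_release(TMState(), SynapseSpec(weight=1.0), 10.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    isis=st.lists(st.floats(0.5, 500.0), min_size=1, max_size=30),
    U=st.floats(0.05, 1.0),
    tau_rec=st.floats(10.0, 1000.0),
)
def test_tm_resource_bounds_and_rapid_train_monotonicity(isis, U, tau_rec):
    """0 <= x <= 1 always; for an equally spaced rapid train the released
    amplitude never increases from spike to spike."""
    spec = SynapseSpec(weight=1.0, kind="depressing", U=U, tau_rec=tau_rec)
    state = TMState()
    last_amp = None
    amp, state = tm_release(state, spec, math.inf)
    assert 0.0 <= state.x <= 1.0
    for dt in isis:
        amp, state = tm_release(state, spec, dt)
        assert 0.0 <= state.x <= 1.0
        assert 0.0 <= amp <= spec.U * 1.0 + 1e-12
    # rapid equally spaced train: amplitudes non-increasing
    state = TMState()
    for k in range(10):
        amp, state = tm_release(state, spec, math.inf if k == 0 else 2.0)
        if last_amp is not None:
            assert amp <= last_amp + 1e-12
        last_amp = amp


# ---------------------------------------------------------------------------
# Poisson drive
# ---------------------------------------------------------------------------

def test_poisson_counts_and_mean_current():
    sched = DriveSchedule().add_poisson(np.arange(10), 2000.0, 0.13, 0.0, 500.0, "bg")
    trains = generate_poisson_drive(sched, 500.0, 0.1, seed=7)["bg"]
    counts = np.array([len(t) for t in trains])
    assert abs(counts.mean() - 1000.0) < 4 * math.sqrt(1000.0)
    # mean injected current = rate * weight * tau_syn
    expected_pa = 2000.0 / 1000.0 * 0.13 * 2.0
    assert expected_pa == pytest.approx(0.52)


def test_poisson_steady_state_depolarization_by_simulation():
    """rate * w * tau_syn * tau_m / C gives the mean depolarization."""
    net = NetworkGraph()
    pop = net.add_population("N", 50, NeuronParams(V_th=1e6))  # never spikes
    drive = DriveSchedule().add_poisson(pop.gids, 2000.0, 0.13, 0.0, 400.0, "bg")
    raster = run_network(net, drive, 400.0, seed=3, record_v=tuple(pop.gids[:50]))
    v_late = np.mean([raster.v_trace[g][2000:] for g in pop.gids[:50]])
    assert v_late == pytest.approx(10.4, rel=0.05)


def test_poisson_determinism_same_seed():
    sched = DriveSchedule().add_poisson(np.arange(5), 500.0, 0.1, 0.0, 200.0, "x")
    a = generate_poisson_drive(sched, 200.0, 0.1, seed=11)["x"]
    b = generate_poisson_drive(sched, 200.0, 0.1, seed=11)["x"]
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta, tb)


def test_negative_rate_rejected():
    with pytest.raises(InvalidArgumentError):
        DriveSchedule().add_poisson(np.arange(3), -1.0, 0.1, 0.0, 10.0, "bad")


# ---------------------------------------------------------------------------
# run_network
# ---------------------------------------------------------------------------

def _two_neuron_chain(weight=50.0, delay=1.5):
    net = NetworkGraph()
    net.add_population("A", 1, DEFAULT_NEURON)
    net.add_population("B", 1, DEFAULT_NEURON)
    net.connect("A->B", "A", "B", [0], [0], [weight], SynapseSpec(weight=weight, delay=delay))
    return net


def test_no_drive_no_spikes():
    raster = run_network(_two_neuron_chain(), None, 100.0, seed=0)
    assert raster.n_events == 0


def test_chain_matches_single_neuron_oracle():
    """Network B-spike times equal lif_response driven by A's spike train."""
    net = _two_neuron_chain(weight=50.0)
    drive = DriveSchedule().add_current(np.array([0]), 8.0, 0.0, 300.0, "dc")
    raster = run_network(net, drive, 300.0, seed=0)
    a_local, a_times = raster.select("A")
    b_local, b_times = raster.select("B")
    assert len(a_times) > 3 and len(b_times) > 0
    _, _, b_ref = lif_response(
        DEFAULT_NEURON, SynapseSpec(weight=50.0, delay=1.5), a_times, 300.0, 0.1
    )
    np.testing.assert_allclose(b_times, b_ref, atol=1e-9)


def test_replay_equivalent_to_live_presynaptic_spikes():
    """A replayed source train drives the target exactly like a live one."""
    net = NetworkGraph()
    net.add_population("B", 1, DEFAULT_NEURON)
    times = np.array([10.0, 12.0, 30.0, 55.0])
    src = ReplaySource(
        n_pre=1,
        pre_ids=np.zeros(len(times), dtype=int),
        times=times,
        indptr=np.array([0, 1]),
        post_gids=np.array([0]),
        weights=np.array([50.0]),
        delay=1.5,
    )
    raster = run_network(net, None, 100.0, seed=0, replay=(src,))
    _, _, ref = lif_response(DEFAULT_NEURON, SynapseSpec(weight=50.0, delay=1.5), times, 100.0, 0.1)
    _, b_times = raster.select("B")
    np.testing.assert_allclose(b_times, ref, atol=1e-9)


def test_network_determinism_and_refractoriness():
    net = _two_neuron_chain(weight=30.0)
    drive = DriveSchedule().add_poisson(np.array([0]), 3000.0, 0.5, 0.0, 500.0, "bg")
    r1 = run_network(net, drive, 500.0, seed=42)
    r2 = run_network(net, drive, 500.0, seed=42)
    np.testing.assert_array_equal(r1.gids, r2.gids)
    np.testing.assert_array_equal(r1.times, r2.times)
    assert r1.n_events > 10
    validate_raster(r1, t_ref_abs=DEFAULT_NEURON.t_ref_abs)


def test_delay_below_dt_rejected():
    net = _two_neuron_chain(delay=0.05)
    with pytest.raises(InvalidArgumentError):
        run_network(net, None, 10.0, dt=0.1, seed=0)


def test_membrane_floor_bounds_hyperpolarization():
    p = NeuronParams(V_min=-10.0)
    syn = SynapseSpec(weight=-100.0, delay=1.5)
    _, V, _ = lif_response(p, syn, [5.0], 50.0, 0.1)
    assert V.min() >= -10.0


def test_delta_psp_mode_jumps_then_decays():
    p = NeuronParams()
    syn = SynapseSpec(weight=5.0, delay=1.5)
    t, V, _ = lif_response(p, syn, [10.0], 60.0, 0.1, psp_mode="delta")
    k = int(np.argmax(V))
    assert t[k] == pytest.approx(11.5, abs=0.15)  # abrupt increase at arrival
    assert V[k] == pytest.approx(5.0 * syn.tau_syn / p.C, rel=0.05)
    # pure exponential decay afterwards with tau_m
    assert V[k + 200] == pytest.approx(V[k] * math.exp(-20.0 / p.tau_m), rel=0.02)
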