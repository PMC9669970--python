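"""Neuron and synapse parameter containers.

All neurons in both integrators are current-based leaky integrate-and-fire
(LIF) units with exponentially decaying postsynaptic currents (PSCs).  The
default constants describe a cell with C = 1 pF, a 20 mV spike threshold,
a 20 ms membrane time constant, and resting/reset potentials at 0 mV.
Synapses are either static or depressing; depressing synapses follow the
depression-only Tsodyks-Markram rule with release fraction ``U`` and
recovery time constant ``tau_rec``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane constants.

    Parameters
    ----------
    C : float
        Membrane capacitance in pF.
    V_th : float
        Spike threshold in mV.
    tau_m : float
        Membrane time constant in ms.
    E_L : float
        Resting potential in mV.
    V_reset : float
        Post-spike reset potential in mV.
    t_ref_abs : float
        Absolute refractory period in ms.  During refractoriness the
        membrane is clamped at ``V_reset`` while synaptic currents keep
        evolving.
    V_min : float
        Lower bound of the membrane potential in mV.  Current-based
        synapses have no reversal potential, so strong convergent
        inhibition would otherwise hyperpolarize a cell arbitrarily far
        and freeze it for hundreds of ms; the floor plays the role of the
        inhibitory reversal potential and keeps recovery times in the
        biological range.  Set to ``-inf`` to disable.
    """

    C: float = 1.0
    V_th: float = 20.0
    tau_m: float = 20.0
    E_L: float = 0.0
    V_reset: float = 0.0
    t_ref_abs: float = 2.0
    V_min: float = -10.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InvalidArgumentError(f"C must be positive, got {self.C}")
        if self.tau_m <= 0:
            raise InvalidArgumentError(f"tau_m must be positive, got {self.tau_m}")
        if not (self.V_reset <= self.E_L < self.V_th):
            raise InvalidArgumentError(
                f"require V_reset <= E_L < V_th, got "
                f"({self.V_reset}, {self.E_L}, {self.V_th})"
            )
        if self.t_ref_abs < 0:
            raise InvalidArgumentError("t_ref_abs must be non-negative")
        if self.V_min > self.V_reset:
            raise InvalidArgumentError("V_min must not exceed V_reset")


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse type: kind, PSC amplitude, delay and kinetics.

    ``weight`` is the signed PSC amplitude in pA (the jump of the synaptic
    current when a presynaptic spike arrives).  ``delay`` is the conduction
    delay in ms and must be a positive integer multiple of the simulation
    step.  ``tau_syn`` is the PSC decay constant.  For ``kind="depressing"``
    the release fraction ``U`` and recovery constant ``tau_rec`` must be
    set; the transmitted amplitude of a spike is ``weight * U * x`` where
    ``x`` is the available synaptic resource (see :func:`locint.engine.tm_release`).
    """

    weight: float
    delay: float = 1.5
    tau_syn: float = 2.0
    kind: str = "static"
    U: float = 0.2
    tau_rec: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("static", "depressing"):
            raise InvalidArgumentError(f"unknown synapse kind {self.kind!r}")
        if self.delay <= 0:
            raise InvalidArgumentError("delay must be positive")
        if self.tau_syn <= 0:
            raise InvalidArgumentError("tau_syn must be positive")
        if self.kind == "depressing":
            if not (0 < self.U <= 1):
                raise InvalidArgumentError("U must lie in (0, 1] for depressing synapses")
            if self.tau_rec is None or self.tau_rec <= 0:
                raise InvalidArgumentError("tau_rec must be positive for depressing synapses")

    def with_weight(self, weight: float) -> "SynapseSpec":
        return replace(self, weight=weight)


#: Membrane constants shared by every neuron in both integrators.
DEFAULT_NEURON = NeuronParams()

#: Depression recovery constant for the discrete integrator (ms).
TAU_REC_DISCRETE = 200.0
#: Depression recovery constant for the continuous (ring) integrator (ms).
TAU_REC_CONTINUOUS = 500.0
#: Release fraction of depressing synapses.
U_DEPRESSION = 0.2
#: PSC decay time constant (ms), common to all synapses.
TAU_SYN = 2.0
#: Default conduction delay (ms).
DELAY_DEFAULT = 1.5
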