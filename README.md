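# locint — location-code neural integrators

`locint` is a spiking-network simulator and analysis toolkit for
*location-code* evidence integration in perceptual decision-making.  It is
aimed at computational neuroscientists who want to study how cortical
circuits can accumulate sensory evidence losslessly — retaining it through
temporal gaps in the input — and how downstream populations convert the
stored quantity into the ramping or stepping firing profiles seen in
parietal cortex during decisions.

## The models

A classic rate-code integrator obeys

```
tau_m dF/dt = -F + F_max / (1 + exp(-beta (r F + E - theta)))
```

and stores evidence as a graded rate `F`.  Its fixed points `g(F*) = F*`
(stable iff `g'(F*) < 1`) collapse onto at most two attractors — quiescent
and saturated — so any intermediate level is lost when the input pauses.
`locint.rate_model` reproduces this with fixed-point finding, stability
classification and one-parameter bifurcation scans.

The alternative stores evidence as the *position* of a bump of elevated
spiking on a topographic lattice.  Two spiking implementations are
provided, both built from current-based LIF neurons (C = 1 pF, V_th =
20 mV, tau_m = 20 ms, exponential PSCs with tau_syn = 2 ms) and
Tsodyks–Markram depressing synapses (`U = 0.2`; transmitted amplitude
`A·U·x`, resource recovery `x' = 1 − (1 − x) e^(−Δt/τ_rec)`):

* **Discrete integrator** — 17 populations of 400 pyramidal + 16 SST
  cells plus two pools of 1,088 PV cells.  Depressing within-population
  recurrence makes the active population exhaust itself and hand activity
  to its neighbor (integration); during an input gap the SST cells are
  disinhibited and freeze the sequence in place (retention).
* **Continuous ring integrator** — 4,000 coordinates with Pyr, SST1 and
  SST2 at each, plus two PV pools.  The bump travels clockwise at a speed
  that grows with the input strength `alpha`
  (`I_sustained = 400 + 100·alpha` Hz), is vetoed from moving backwards by
  SST2's asymmetric inhibition, and is locked in place during gaps by
  SST1.

**Readout** populations receive *gradient connections* — probability
`p0·n/4000` for presynaptic coordinate `n` — so their firing rate encodes
bump position.  A two-integrator race gives a 2-choice decision variable;
a single recurrent readout population reproduces population ramping while
individual cells show either ramping or abrupt stepping ("PSR") profiles,
classified by sigmoid fits `S(t) = c/(1+e^{−a(t−b)}) + d` with R² ≥ 0.85.

## Worked example

Scan the rate model's fixed points against the external input, then run
the discrete integrator through the two-epoch gap protocol:

```
$ locint bifurcate --param E --range -10:10 --out out/bif
max simultaneously stable fixed points: 2

$ head -4 out/bif/branches.tsv
E       F_star  stability       saddle_node
-10.0   0.0005510179745576993   stable  False
-10.0   10.625204128884308      unstable        False
-10.0   19.99850082791405       stable  False
```

At `E = −10` the model is bistable (stable branches near 0 and near
`F_max = 20` separated by an unstable root): the rate code can only hold
"nothing" or "everything", which is why a gap in the input destroys a
graded level.

```python
from locint.discrete import (DiscreteConfig, StimulusProtocol,
                             run_discrete_experiment, activated_populations,
                             gap_holding_population, resumption_population)

raster, rates = run_discrete_experiment(
    DiscreteConfig(), StimulusProtocol(), duration=1100.0, seed=1)
print(activated_populations(rates))      # [1, 2, 3, 4, 5, 6, 7, 8]
print(gap_holding_population(rates))     # 5
print(resumption_population(rates))      # 6
```

Populations 1–5 activate in order during the first stimulus epoch
(100–300 ms), population 5 alone stays active through the 300–800 ms gap
(the stored evidence), and the sequence resumes at population 6 when the
second epoch starts — lossless integration.  The raster and the 50-ms
binned population-rate table are ordinary pandas/NumPy objects; the same
experiments are available from the CLI (`locint run-discrete --preset
discrete-gap`, `locint run-continuous --preset ring-gap`, `locint sweep`,
`locint run-readout`, `locint analyze …`), each writing TSV outputs plus
a manifest that makes the run reproducible from its output directory.

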