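# Methods

This note documents the models implemented in `locint`, the numerical
choices behind the engine, the design decisions taken where the circuit
description leaves parameters open, and the known limitations of the
reproduction.

## The scientific problem

Perceptual decisions are thought to rest on temporal integration of noisy
sensory evidence.  The classic circuit model is a *rate-code* integrator —
a recurrent population whose firing rate grows with accumulated evidence —
but such integrators require the recurrent gain to cancel the membrane
leak exactly, and they cannot hold a graded level of activity across a
temporal gap in the evidence.  `locint` implements the alternative: a
*location-code* integrator, in which evidence is stored as the position of
a localized packet of elevated spiking ("bump") on a topographically
organized lattice.  The bump travels while evidence arrives and is locked
in place by lateral inhibition when the evidence pauses, which makes the
integrator lossless by construction.  Downstream "readout" populations
convert bump position into firing rate through *gradient connections*
(connection probability proportional to the presynaptic coordinate) and
reproduce both classic ramping and stepping ("PSR") response profiles
depending on how densely they are wired.

## Neuron and synapse model

All cells are current-based leaky integrate-and-fire neurons with
exponentially decaying postsynaptic currents:

```
C dV/dt = -C (V - E_L)/tau_m + I_syn + I_dc        tau_m = 20 ms, C = 1 pF
dI_syn/dt = -I_syn / tau_syn                       tau_syn = 2 ms
```

Spike threshold 20 mV, reset and rest at 0 mV, conduction delay 1.5 ms
unless noted.  The subthreshold system is linear, so the engine advances
it with the exact exponential propagator of the 2x2 system per time step
(`dt = 0.1 ms` by default); subthreshold trajectories are exact at the
grid points for any step size, and thresholds are resolved at step
boundaries.  A presynaptic spike increments the target's synaptic current
by the (possibly depressed) PSC amplitude at spike time + delay.

Two parameters of the neuron model are not fixed by the circuit
description and are exposed on every model config:

* **Absolute refractory period** `t_ref_abs`.  Default 2 ms for single
  cells and the ring integrator.  For the discrete integrator the default
  is 3.25 ms: the refractory period caps the active population's firing
  rate and thereby sets the handoff cadence of the winner-take-all
  sequence; 3.25 ms yields one handoff every ~50 ms, i.e. five
  populations per 200-ms stimulus epoch.
* **Membrane floor** `V_min`.  Current-based synapses have no reversal
  potential, so convergent inhibition can drive a cell hundreds of mV
  below rest, freezing it for hundreds of ms of recovery.  `V_min` plays
  the role of the inhibitory reversal potential.  It is applied
  selectively: SST cells get a floor at -30 mV in both integrators (they
  are crushed by PV2 while evidence is present, and the retention circuit
  only works if they can re-engage within a few ms of a gap onset); Pyr
  and PV membranes are left unbounded, because their deep
  post-volley hyperpolarization is load-bearing — it stores the identity
  of the next population in line and keeps competitors out of the race.

Depressing synapses use the depression-only Tsodyks–Markram rule.  Between
presynaptic spikes the resource recovers as
`x' = 1 - (1 - x) exp(-dt/tau_rec)`; a spike transmits `A * U * x'` and
leaves `x' (1 - U)`.  `U = 0.2` everywhere; `tau_rec` is 200 ms in the
discrete integrator and 500 ms in the ring.  Because recovery depends only
on the presynaptic train, one state per (projection, presynaptic cell)
suffices, which the engine exploits.

**Efficacy convention.**  For the discrete integrator the tabulated
strength (1.8 pA) is the absolute efficacy `A` (first spike transmits
`A*U` = 0.36 pA).  For the ring integrator the tabulated strength
(0.52 pA) is the PSC amplitude of a fully recovered synapse
(`A = 0.52/U` = 2.6 pA).  The two readings were discriminated
empirically: under the first convention the ring's lateral excitation
tops out near 4 mV of sustained drive and no bump can recruit its front
(the packet dies wherever it is seeded), while under the second the
discrete sequence never terminates (a population's recurrence can no
longer be exhausted by depression).  Each model is built with the
convention under which its documented behavior exists.

## Discrete integrator

Seventeen populations of 400 Pyr + 16 SST cells, plus two PV pools of
1,088 cells.  Within a population, Pyr cells are all-to-all coupled by
depressing synapses; each population excites the next one weakly
(p = 0.2, 0.12 pA, 10 ms delay) with a periodic boundary.  PV1 receives
from all Pyr and inhibits everything (feedback, winner-take-all); PV2 is
purely stimulus-driven and silences the SST cells while evidence is
present; SST cells of each population inhibit the Pyr cells of every
*other* population.  Per-connection weights are Gaussian with SD = 10% of
the mean, sign-clipped at zero.

Mechanism: the onset input ignites population 1; its depressing
recurrence exhausts itself while its activity charges the next population
through the delayed feedforward link; PV1 feedback normally vetoes
everyone else.  Handoff happens when the active population collapses;
during a gap, PV2 falls silent, the SST cells of the active population are
released and freeze the sequence in place; when evidence returns, PV2
silences SST again and the sequence resumes at the next population.

Two table ambiguities were resolved as follows:

* The within-population block lists PV1 self-inhibition twice (p = 0.3
  and p = 0.1, both -0.72 pA).  Both projections are instantiated, PV2
  receives no self-inhibition.  This is not cosmetic: with the two
  tabulated in-degrees, the feedback inhibition recruited per Hz of
  pyramidal activity (through PV1) exactly cancels the feedforward
  excitation per Hz a successor population receives, so no successor can
  ever ignite while the winner lives.  The second projection breaks the
  cancellation in favor of ordered handoff, and it simultaneously makes
  the PV1 feedback veto of the second-epoch onset work (removing the
  Pyr→PV1 limb reactivates population 1 — the documented control).
* SST count: the description gives both 16 per population and a total of
  544 (= 17 x 32).  The default is 32 per population: the doubled SST
  pool silences PV1 reliably during a gap, which protects the holding
  population for the full 500 ms (with 16, retention survives only about
  half the time).  `sst_per_pop` is configurable.

Both stimulus presentations carry their own 100-ms onset drive to
population 1; during normal operation PV1 feedback suppresses its effect,
which is exactly what the `no_pv1_feedback` control demonstrates.

A population counts as "activated" when its mean rate exceeds 5 Hz per
cell in at least one 50-ms bin; the gap holder is the unique population
above that threshold in ≥ 90% of gap bins.

## Continuous (ring) integrator

4,000 Pyr, SST1 and SST2 cells share a circular lattice; PV1/PV2 are
unstructured pools of 1,000.  Pyr cells excite neighbors within circular
distance 200 through depressing synapses; Pyr→SST1/SST2 are one-to-one at
equal coordinate with 11.7 pA (one bump spike fires the partner); SST1
inhibits Pyr at offsets +200…+3799 (in-degree exactly 3,600; the
asymmetric half-open window is the only reading that reproduces the
tabulated in-degree); SST2 inhibits the 400 coordinates *behind* it
(offsets −400…−799), vetoing counterclockwise propagation.  The sustained
drive follows `I_sustained = 400 + 100*alpha` Hz for the PV pools and four
times that for Pyr; all external synapses weigh 0.13 pA.

Protocol and initial-condition choices (all configurable):

* **Silent pre-stimulus window.**  The Pyr background (3,850 Hz x 0.13 pA
  x 2 ms x 20 ms/pF = 20.02 mV) parks every cell exactly at rheobase.  A
  background-only warm-up period therefore always nucleates a bump at a
  noise-chosen location within ~100 ms, and the SST1 lock then holds it
  there — the onset can no longer dictate where integration starts.  The
  background is switched on together with the first stimulus epoch, which
  leaves the pre-stimulus window genuinely silent.
* **Onset head start.**  The onset burst (3,000 Hz to 100 cells,
  configurable) leads the sustained epochs by 50 ms, so the seeded zone
  crosses threshold and recruits its PV1 veto before the rest of the
  lattice completes its charge-up transient; bump formation is thereby
  pinned to the seeded zone on every seed.
* **Seed origin.**  Ignition recruits the seed's neighbors on both sides
  before the SST2 veto engages, so a seed at coordinate 0 smears across
  the periodic wrap point and briefly drives the readout's
  highest-weight synapses.  The seed is placed at coordinate 400
  (`onset_origin`), one neighborhood-width past the wrap.
* **Quenched background heterogeneity.**  With a uniform background all
  cells share one operating point at rheobase and the lattice fires in
  global volleys.  Per-cell background rates are drawn one-sidedly below
  the nominal value (half-normal, CV 0.2): the spread desynchronizes the
  population without lifting any cell above rheobase (which would make
  the unstimulated lattice spontaneously active and break retention).

Mechanism notes: with `tau_rec = 500 ms` a *stationary* bump cannot
sustain itself under stimulus (the product `rate x resource` saturates
below the PV1-imposed threshold) — only a moving bump, whose front
constantly enters fresh synaptic territory, survives.  Conversely, during
a gap PV1 falls silent (no stimulus drive) and a low-rate stationary bump
becomes stable, held laterally by SST1.  Loop algebra also shows that a
bump wider than ~170 coordinates cannot recruit its front against the
PV1 feedback, which is why the narrow (100-cell) onset is structural
rather than cosmetic.

## Readout circuits

Gradient projections connect Pyr coordinate `n` to each readout cell with
probability `p0 * n / 4000`.  The race circuit wires each integrator to
the E cells of its own readout population and the I cells of the opposite
one; the single-readout circuit is one E population (400 cells) with
recurrent E→E synapses drawn with probability `p_conn`.  All readout
synapses are static; every readout cell receives a 200-Hz external drive
at 1.3 pA (a 10.4 mV working point).  Readout simulations replay the
stored integrator raster through freshly drawn gradient synapses — exact,
because the readout does not project back — so a whole `p0 x p_conn` grid
reuses one integrator run.

The integrator→readout and readout-internal strengths are not constrained
by the circuit tables.  They were calibrated with
`scripts/calibrate_readout.py` (defaults: integrator→E = integrator→I =
0.03 pA, I→E = −0.4 pA, E→E = 0.1 pA, `p_conn` = 0.15) to maximize the
dense/sparse (`p0` = 1.0 vs 0.1) dissociation of per-cell time
correlations while keeping the recurrent population subcritical at
moderate `p_conn`.  The decision-onset statistic for difference traces is
the first 25-ms bin whose E1−E2 rate difference exceeds a threshold
(default 5 Hz) and stays positive for four consecutive bins.

## Rate model

The one-population rate model `tau_m dF/dt = -F + F_max / (1 + exp(-beta
(r F + E - theta)))` (defaults F_max = 20, beta = 1, theta = 0.5, r = 1,
E = 0, tau_m = 20 ms) is analyzed by sign-change bracketing of
`g(F) - F` on a 4,001-point grid over `[-0.05 F_max, 1.05 F_max]`,
bisection to 1e-8, and stability classification by `g'(F*) < 1`;
`beta` acts purely as a deterministic gain slope.  One-parameter scans
flag saddle-node events where the root count changes.  Trajectories use
fixed-step RK4 with optional piecewise-constant input schedules.

## Analysis conventions

Half-open time bins `[start, stop)`.  Ramping statistics: per-cell OLS of
25-ms-binned rates on bin centers over 100–550 ms, two-sided slope test,
significance at p < 0.05.  Quiescent/active split: `T` = start of the
first bin whose rate reaches the mean over all bins (ties cross upward).
Sigmoid (stepping) fits on 50-ms bins: deterministic multi-start
nonlinear least squares (`d0` = min rate, `c0` = range, `b0` = split
time, `a0` in {0.01, 0.05, 0.2}/ms), PSR classification at R² ≥ 0.85;
constant series have R² defined as 0 and are excluded.  The travel-time
statistic histograms the 400 highest-coordinate cells in 10-ms bins over
the whole run and reports the first bin exceeding mean + 2 SD relative to
stimulus onset; the crossing search can be restricted to start after the
network's charge-up transient (the threshold itself always uses all
bins).  Bump tracking uses the circular mean coordinate in 20-ms windows
(NaN below 5 spikes).

## Problem sizes of the test suite

The full-size models are used everywhere.  Stochastic checks are scaled
in repetition count, not in network size: the discrete sequence check
uses 10 seeds; the travel-time sweep uses alpha in {2, 6, 10} with two
seeds and 2.4-s runs; the readout dissociation uses three integrator
seeds; the PSR grid is 2 x 3 (`p0` in {0.1, 0.5}, `p_conn` in
{0.15, 0.25, 0.35}) driven by one integrator run.

## What the reproduction does and does not achieve

Reproduced: the rate-model bifurcation structure; all structural counts;
the discrete sequence–hold–resume pattern (ordered activation in 10/10
seeds, holder at population 5 in 10/10, resumption at population 6 in
~8/10, the full 8-activated/hold-5/resume-6 pattern in ~5/10 — the
near-misses stop at population 7 because resumption starts late); the
synapse-type controls
(static synapses abolish propagation and bridging — activity stalls in
populations 1–2 rather than 1 alone, because the full-strength static
recurrence also ignites the immediate neighbor; PV1-feedback removal
reactivates population 1); a clockwise-only propagating ring bump pinned
to the onset zone with travel time strictly decreasing in the input
strength; gap retention with SST1 gating and clockwise resumption; a
dense/sparse readout dissociation in the expected direction; PSR counts
that grow with `p0` and with moderate `p_conn`.

Not reproduced quantitatively: the ring bump propagates in lurching
volley cycles (~20 ms) rather than asynchronously.  The volley mode is
robust here — the loop through the homogeneous PV1 pool discharges
all-or-none, and no printed parameter desynchronizes it — and it has
three downstream consequences: held bumps creep by 200–400 coordinates
per 500-ms gap instead of < 100 (within one bump width, but above the
strict criterion); SST1 leaks some spikes in the first ~25 ms of each
stimulus epoch before PV2 charges, so the gap/stimulus SST1 ratio is
~1–2 rather than ≥ 10; and readout cells phase-lock to the volleys, so
per-cell time-correlation counts at dense connectivity reach only ~20/400
rather than ~310/400, and population 25-ms-bin regressions are swamped by
the volley rhythm.  The PSR count also keeps rising with `p_conn` into an
abrupt reverberation transition instead of falling past an interior
maximum: in a purely excitatory readout pool the supercritical transition
is itself a step, which the sigmoid classifier embraces rather than
rejects.  These gaps are documented test failures, not hidden ones.

The synthetic rasters used by the analysis tests emulate known ground
truth (periodic trains, drifting clusters, planted steps); they contain
no network correlations, so passing those tests validates the statistics,
not the simulator.
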