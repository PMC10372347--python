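# Methods

## Model

`wtanet` simulates a local cortical decision circuit of N = 480 leaky
integrate-and-fire neurons — 384 pyramidal cells and 96 fast-spiking
interneurons — with conductance-based AMPA, NMDA, and GABA synapses.  Two
selective groups of 96 pyramidal cells (A and B) encode the two choice
alternatives; the remaining 192 pyramidal cells are nonselective.
Connectivity is all-to-all without self-connections.

Subthreshold dynamics of every cell follow

    C_m dV/dt = -g_L (V - V_L) - I_syn(t)

with a spike emitted and V reset to V_reset when V crosses V_th, followed by
an absolute refractory period during which V is clamped at V_reset.
Defaults: V_L = -70 mV, V_th = -50 mV, V_reset = -60 mV; pyramidal cells
C_m = 500 pF, g_L = 25 nS, tau_ref = 2 ms (membrane time constant 20 ms);
interneurons 200 pF, 20 nS, 1 ms (10 ms).

The synaptic current splits into external AMPA, recurrent AMPA, recurrent
NMDA, and recurrent GABA terms, each of the form g · (V − V_rev) · Σ w_j s_j.
AMPA and GABA gating variables jump by +1 per presynaptic spike and decay
with tau = 2 ms and 5 ms.  NMDA gating uses the two-variable scheme
dx/dt = −x/tau_rise + Σδ, ds/dt = −s/tau_decay + α x (1 − s) with
tau_rise = 2 ms, tau_decay = 100 ms, α = 0.5 /ms, so s saturates at 1 under
sustained drive, and the NMDA conductance is attenuated by the magnesium
block 1/(1 + Mg·exp(−0.062 V)/3.57).  All recurrent synapses have a 5-ms
conduction latency.  Every cell receives an independent external Poisson
train at 2.4 kHz through its external-AMPA channel.

Recurrent pyramidal→pyramidal weights are structured: w+ (> 1) within a
selective group, w− < 1 between the two groups and from nonselective onto
selective cells, 1 elsewhere, with w− = 1 − f(w+ − 1)/(1 − f) for
f = group_size/N_E = 0.25, which keeps the mean recurrent drive in the
spontaneous state independent of w+.  All weights involving interneurons
are 1.

### Magnesium and the pyramidal recurrent-AMPA conductance

Two parameter values sometimes associated with this architecture are
dynamically untenable, and the working set replaces them:

* Mg defaults to 1 mM (the canonical concentration for this synaptic
  model).  At 11 mM the NMDA channel is essentially silenced at
  subthreshold voltages and no choice of the remaining parameters yields a
  stable spontaneous state.
* The pyramidal recurrent-AMPA conductance defaults to 0.05 nS, matching
  its interneuron counterpart in magnitude.  At 0.5 nS, fast recurrent
  excitation exceeds anything the interneurons (recruited at 0.04 nS) can
  balance and every excitatory cell locks at its refractory-limited rate
  (~380 spikes/s) regardless of w+, with or without magnesium block.

The unmodified table remains available through `network.conductances_for`.

### Network-size compensation

The per-synapse conductance table corresponds to the canonical
2000-neuron realization of this architecture.  An all-to-all network of N cells sums N-
proportional recurrent input, so the shipped default multiplies the
recurrent conductances (g_rec_AMPA, g_NMDA, g_GABA; external drive
untouched) by REFERENCE_SIZE/N = 2000/480 ≈ 4.17 — the standard mean-field
size scaling.  Without it the 480-cell network cannot hold persistent delay
activity at any w+ ≤ 2.2: the winner decays back to the spontaneous state
after stimulus offset.  The factor is exposed as
`TrialConfig.recurrent_scale`.

## Integration

A fixed-step Heun (second-order Runge–Kutta) scheme with dt = 0.02 ms
advances the coupled gating + membrane system.  Per step: (1) spikes due
this step are delivered as discrete +1 increments to the gating variables
(preserving the per-spike jump semantics exactly under RK2); (2) gating and
membrane equations advance one Heun step, with the stage-2 synaptic current
evaluated at the stage-2 gating values; (3) threshold, reset, and refractory
logic are applied and emitted spikes are queued for delivery exactly
latency/dt = 250 steps later.  s_NMDA is clamped to [0, 1] after each step
to remove second-order overshoot of its invariant bound.  Refractory
periods are integer step counts (100 pyramidal, 50 interneuron).

Two implementations of this scheme exist: a readable dense-matrix NumPy
stepper (`dynamics.ReferenceNetwork`) and a numba kernel (`_kernel`) that
exploits the block structure of the weight matrix (per-group gating totals
plus a self-term correction) for O(N) cost per step.  The test suite checks
that both produce identical spike rasters and matching state on the same
input.  Poisson input in the kernel is drawn by pool superposition (one
count per rate-homogeneous pool, assigned to uniformly random members),
which is distributionally identical to independent per-cell trains.

All internal quantities use the closed unit system {mV, ms, nS, pF, pA}.

## Trial protocol and statistics

A trial lasts 3000 ms.  A selective stimulus adds 140 Hz to the external
Poisson rate of group A between 500 and 1500 ms.  The increment is the one
free protocol parameter (the corresponding experimental quantity is not a
printed constant); it was calibrated once, by the procedure in
`scripts/calibrate_stimulus.py`, as the smallest scanned value whose median
reaction time in the default network (V_L = −70 mV, w+ = 1.9) falls in the
200–600 ms band; the shipped value gives a median of ~250 ms.  Weaker
stimuli are preferred because they leave the reaction time dominated by
intrinsic excitability rather than by the drive.

Population rates are spike counts per group in non-overlapping 20-ms
windows anchored at t = 0, divided by group size and window length.  The
reaction time is the time from stimulus onset to the first window in which
a selective group reaches 25 spikes/s; the first group to cross is the
winner; trials with no crossing have no reaction time and are excluded from
means (in the low-RMP conditions this is the typical outcome, mirroring the
no-decision cells of the sweep heatmap).  A trial counts as showing
persistent delay activity when the winner's mean rate over the final 500 ms
(after stimulus offset) is at least 10 spikes/s; the criterion rate is a
package choice (no printed value exists) and is configurable.  Reaction
times are reported at window centers, so they carry ±10 ms granularity.

Resting-potential manipulations set the leak potential V_L of both cell
classes (flag `rmp_pyramidal_only` restricts to pyramidal cells; with it
the hyperpolarized conditions fail to ignite at the calibrated stimulus
because inhibition is undiminished, so the both-classes default stands).
The inhibitory reversal potential stays at −70 mV throughout.

Sweeps derive one seed per (cell, trial) by hashing (base seed, V_L, w+,
trial index), so any single cell reruns bitwise identically regardless of
grid shape.

## Single-cell model

One pyramidal-parameter cell receives 1000 excitatory and 250 inhibitory
independent 10-Hz Poisson trains.  Excitatory trains drive AMPA and NMDA
gating with identical spike times; per-train conductances are
g_AMPA = 0.1 nS, g_GABA = 0.5 nS, g_NMDA = 0.05 nS × strength_scale —
values chosen once so the baseline (scale 1, tau_decay 100 ms) rests a few
mV above V_L and well below threshold; they are not constrained by the
network's per-recurrent-synapse table.  Spiking is disabled by default
(the emulated recordings showed no spontaneous spikes) and the RMP is the
mean potential over the final 100 ms after a 500-ms settling period.

The analytic helper `nmda_mean_field_saturation` returns the deterministic
fixed point s* = α x* τ_decay/(1 + α x* τ_decay), x* = rate · τ_rise.  This
fixed point is an upper bound on the stochastic time average, not its
limit at low rates: at 10 Hz per train, spikes are rare on the 100-ms decay
scale, the gating decays between them while the saturating drive clips
during them, and the measured time average is ≈ 0.78 of the fixed point.
The ratio rises toward 1 as rates grow (≈ 0.90 at 40 Hz, 0.95 at 80 Hz).
Tests assert this measured behavior.

## What the synthetic inputs do and do not emulate

All inputs are internally generated Poisson processes: stationary
background drive, a rectangular selective rate step, and (single cell)
stationary presynaptic trains.  Real cortical input is neither stationary
nor Poisson (up/down states, correlations, adaptation), stimuli are not
rectangular, and the circuit lacks plasticity, dendritic nonlinearities,
and conductance heterogeneity.  Passing tests therefore certify the
attractor mechanism and its parameter dependence, not quantitative
biological rates.

## Problem sizes and known limitations

Shipped experiment sizes: persistence grid 6 × 10 trials, effect-size
contrasts 10 trials per condition, low-vs-high RMP comparison 20 trials per
condition, plateau measurement 5 trials, single-cell orderings 20 seeds per
condition — one 3-s network trial integrates 150 000 steps in a few
seconds of wall time through the compiled kernel.

Known limitations of the realized regime (documented, not tuned away):

* The winner's delay-period plateau at w+ = 2.2 is ~40 spikes/s.  Scans of
  the AMPA/NMDA/GABA/interneuron-recruitment scale planes found no stable
  competitive regime with a winner-only plateau near 100 spikes/s: strong
  fast recurrence either destabilizes the spontaneous state or produces
  symmetric both-groups-active states; feedback inhibition otherwise pins
  the winner near 40–50 spikes/s.
* The persistence boundary on the default grid falls at w+ = 1.8, one grid
  step above the nominal 1.7, and reaction times just below the boundary
  are strongly inflated, so the reaction-time contrast between w+ = 1.7
  and 2.2 (~170–200 ms) is larger than the nominal 40 ms.  The ordering
  that matters — the resting-potential contrast exceeds the
  recurrent-weight contrast — holds.
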