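# wtanet

A spiking winner-take-all attractor network for studying how the **resting
membrane potential (RMP)** and the **recurrent synaptic strength** shape the
speed of perceptual decisions, plus a companion single-cell model showing
how slow NMDA-receptor input elevates the RMP.

The posterior parietal and prefrontal cortices ramp their population
activity at different speeds during decision tasks, and their layer-5
pyramidal cells rest at different membrane potentials.  This package asks,
in a mechanistic circuit model: which matters more for the ramping speed —
how depolarized the cells sit, or how strongly they excite each other?

## Model

The circuit is a 480-neuron leaky integrate-and-fire network (384 pyramidal
cells, 96 interneurons) with conductance-based synapses:

- membrane: `C_m dV/dt = -g_L (V - V_L) - I_syn`, threshold −50 mV, reset
  −60 mV; the leak potential `V_L` plays the role of the RMP;
- synapses: external AMPA (independent 2.4-kHz Poisson drive per cell),
  recurrent AMPA (τ = 2 ms), recurrent NMDA (rise 2 ms, decay 100 ms,
  saturating gating, voltage-dependent Mg²⁺ block
  `1/(1 + Mg e^(−0.062V)/3.57)`), recurrent GABA (τ = 5 ms); 5-ms latency;
- structure: two selective groups of 96 pyramidal cells with potentiated
  within-group weights `w₊ > 1`, depressed cross-group weights
  `w₋ = 1 − f(w₊ − 1)/(1 − f)` (f = 0.25), baseline 1 elsewhere.

A selective stimulus (an increment to one group's external Poisson rate)
ignites competition: the stimulated group ramps up while feedback
inhibition suppresses the other (winner-take-all).  The **reaction time**
is the time from stimulus onset until the winner's 20-ms-window population
rate reaches 25 spikes/s; **persistent activity** (≥ 10 spikes/s through
the final 500 ms after stimulus offset) is the model correlate of working
memory.  Integration is fixed-step Heun (RK2) at dt = 0.02 ms, with a
compiled numba kernel validated step-for-step against a dense NumPy
reference implementation.

The single-cell model bombards one pyramidal cell with 1000 excitatory and
250 inhibitory 10-Hz Poisson trains and measures its RMP while the NMDA
decay constant (100 ms vs 2 ms) and NMDA strength are varied.

## Worked example

Simulate one default trial (resting potential −70 mV, w₊ = 1.9, stimulus
to group A at 500–1500 ms):

```
$ wtanet simulate trial --seed 1 --out out/demo
{"reaction_time": 190.0, "winner": "A", "persistent": true, "n_spikes": 15940, ...}
```

Group A crossed 25 spikes/s 190 ms after stimulus onset and held elevated
activity through the delay period — a committed, remembered decision.
`out/demo/` contains the spike raster (TSV), per-population rate traces
(CSV), a summary JSON, and a run manifest that makes the trial bitwise
reproducible.

The single-cell experiment shows the NMDA mechanism:

```
$ wtanet single-cell --tau-nmda 100 --trials 5 --seed 1 --out out/sc
RMP = -63.36 mV (n = 5)
$ wtanet single-cell --tau-nmda 2 --trials 5 --seed 1 --out out/sc2
RMP = -65.72 mV (n = 5)
```

With slow (100-ms) NMDA kinetics the saturating gating sustains a standing
depolarizing current and the cell rests ~2.4 mV higher than with fast
(2-ms) kinetics — slow synaptic input, not input count, elevates the RMP.

Larger canned experiments (the ramping comparison across w₊, the −80 vs
−70 mV reaction-time comparison, the RMP × w₊ reaction-time heatmap, and
the single-cell condition grid) run via:

```
wtanet reproduce fig3|fig4|fig5|fig6 [--scale smoke|full] [--seed N] [--out DIR]
```

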