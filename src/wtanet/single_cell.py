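"""Single neuron under Poisson synaptic bombardment.

Emulates the slice-recording situation in silico: one pyramidal-parameter
cell receives 1,000 excitatory and 250 inhibitory presynaptic trains, each
an independent 10-Hz Poisson process.  Excitatory trains drive AMPA and
NMDA gating with the same spike times; inhibitory trains drive GABA gating.
The NMDA decay time constant and a multiplicative strength scale on the
NMDA conductance are the experimental knobs: slow NMDA kinetics let the
per-train gating saturate and sustain a standing depolarizing current,
which raises the measured resting membrane potential; fast kinetics do not.

Spiking is disabled by default (the recorded cells fired no spontaneous
action potentials), so the trace is a continuous subthreshold fluctuation
and the RMP is read off as a time average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .params import DEFAULT_SYNAPSES, PYRAMIDAL, NeuronParams, SynapseParams

__all__ = ["SingleCellConfig", "SingleCellResult", "run_single_cell",
           "measure_rmp", "nmda_mean_field_saturation"]

#: Per-train peak conductances (nS).  Not constrained by the network's
#: conductance table (those are per-recurrent-synapse values); chosen so the
#: baseline configuration (strength_scale 1, tau_NMDA_decay 100 ms) rests
#: several mV above the leak potential yet well below threshold.
G_AMPA_PER_TRAIN = 0.1
G_GABA_PER_TRAIN = 0.5
G_NMDA_PER_TRAIN = 0.05

#: Transient discarded before the RMP average (ms).
DEFAULT_SETTLE = 500.0
#: Averaging window for the RMP readout (ms), matching a 100-ms
#: zero-current recording epoch.
DEFAULT_RMP_WINDOW = 100.0


@dataclass(frozen=True)
class SingleCellConfig:
    n_exc_inputs: int = 1000
    n_inh_inputs: int = 250
    input_rate: float = 10.0         # Hz per presynaptic train
    tau_NMDA_decay: float = 100.0    # ms; the fast comparison value is 2 ms
    strength_scale: float = 1.0      # multiplier on the NMDA conductance
    duration: float = 1500.0         # ms
    dt: float = 0.02                 # ms
    spiking_enabled: bool = False
    neuron: NeuronParams = field(default_factory=lambda: PYRAMIDAL)
    synapses: SynapseParams = field(default_factory=lambda: DEFAULT_SYNAPSES)
    g_AMPA: float = G_AMPA_PER_TRAIN
    g_GABA: float = G_GABA_PER_TRAIN
    g_NMDA: float = G_NMDA_PER_TRAIN
    settle: float = DEFAULT_SETTLE
    rmp_window: float = DEFAULT_RMP_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exc_inputs <= 0 or self.n_inh_inputs <= 0:
            raise ValueError("input counts must be positive")
        if self.input_rate < 0:
            raise ValueError("input_rate must be nonnegative")
        if self.strength_scale < 0:
            raise ValueError("strength_scale must be nonnegative")
        if self.duration < self.settle + self.rmp_window:
            raise ValueError("duration must cover settle period plus RMP window")


@dataclass
class SingleCellResult:
    time: np.ndarray        # ms
    V: np.ndarray           # mV
    rmp: float              # mV, time-averaged readout
    nmda_gating_mean: float  # mean per-train s_NMDA after settling
    nmda_gating_max: float
    n_spikes: int
    seed: int


def measure_rmp(trace: np.ndarray, dt: float, window: float = DEFAULT_RMP_WINDOW,
                settle: float = DEFAULT_SETTLE) -> float:
    """Mean membrane potential over the final ``window`` ms of the trace,
    provided at least ``settle`` ms precede it."""
    n_window = int(round(window / dt))
    n_settle = int(round(settle / dt))
    if trace.size < n_settle + n_window:
        raise ValueError(
            f"trace of {trace.size * dt:.0f} ms is shorter than settle ({settle}) + window ({window})")
    return float(np.mean(trace[-n_window:]))


def run_single_cell(cfg: SingleCellConfig) -> SingleCellResult:
    """Integrate the bombarded cell and measure its RMP."""
    syn = cfg.synapses
    p = cfg.neuron
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    v_trace, nmda_trace, n_spk, status = _kernel.run_single_cell(
        n_steps, dt,
        cfg.n_exc_inputs, cfg.n_inh_inputs, cfg.input_rate * dt * 1e-3,
        syn.tau_AMPA, cfg.tau_NMDA_decay, syn.tau_NMDA_rise, syn.alpha,
        syn.tau_GABA, syn.Mg, syn.V_E, syn.V_I,
        cfg.g_AMPA, cfg.g_NMDA * cfg.strength_scale, cfg.g_GABA,
        p.V_L, p.V_th, p.V_reset, p.C_m, p.g_L,
        int(round(p.tau_ref / dt)), 1 if cfg.spiking_enabled else 0,
        cfg.seed,
    )
    if status == _kernel.STATUS_NONFINITE:
        raise RuntimeError("single-cell simulation diverged (non-finite state)")
    rmp = measure_rmp(v_trace, dt, cfg.rmp_window, cfg.settle)
    n_settle = int(round(cfg.settle / dt))
    settled = nmda_trace[n_settle:] if nmda_trace.size > n_settle else nmda_trace
    time = (np.arange(n_steps) + 1) * dt
    return SingleCellResult(time=time, V=v_trace, rmp=rmp,
                            nmda_gating_mean=float(np.mean(settled)),
                            nmda_gating_max=float(np.max(nmda_trace)),
                            n_spikes=int(n_spk), seed=cfg.seed)


def nmda_mean_field_saturation(input_rate: float,
                               syn: SynapseParams | None = None,
                               tau_decay: float | None = None) -> float:
    """Steady-state per-train NMDA gating under Poisson-rate mean-field drive.

    With spikes arriving at ``input_rate`` (Hz), the rise variable settles
    at x* = rate * tau_rise, and setting ds/dt = 0 gives

        s* = alpha x* tau_decay / (1 + alpha x* tau_decay)

    monotone in the rate with asymptote 1 — the saturation that makes slow
    NMDA input an effective standing current.
    """
    if input_rate < 0:
        raise ValueError("input_rate must be nonnegative")
    syn = syn if syn is not None else DEFAULT_SYNAPSES
    tau_d = syn.tau_NMDA_decay if tau_decay is None else tau_decay
    x_star = input_rate * 1e-3 * syn.tau_NMDA_rise
    a = syn.alpha * x_star * tau_d
    return a / (1.0 + a)
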