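"""Trial generation: Poisson drive, stimulus timing, trials, and sweeps.

Every neuron receives an independent external Poisson train at
``background_rate`` (2.4 kHz by default).  A trial presents a selective
stimulus as an additive increment to the external rate of one (or both)
selective groups during a fixed window.  The decision variable is the
windowed population rate of each selective group; the first group to reach
the 25 spikes/s threshold after stimulus onset is the winner.

Seeding: ``TrialConfig.seed`` fully determines a trial.  Sweeps derive one
seed per (cell, trial) from the base seed and the cell's parameter values
through a CRC32 counter scheme, so any single cell can be re-run bitwise
identically without running the rest of the grid.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel, analysis
from .network import (GROUP_A, GROUP_B, GROUP_INHIBITORY, GROUP_NONSELECTIVE,
                      REFERENCE_SIZE, build_network)
from .params import (DEFAULT_SYNAPSES, INTERNEURON, PYRAMIDAL, ConductanceRow,
                     ConductanceTable, NeuronParams, SynapseParams)

__all__ = ["StimulusProtocol", "TrialConfig", "TrialResult",
           "external_event_counts", "run_trial", "run_sweep", "derive_seed",
           "DEFAULT_RATE_INCREMENT"]

#: Stimulus strength (Hz added to each stimulated cell's external rate).
#: Calibrated once so that the median reaction time of the default network
#: (V_L = -70 mV, w_plus = 1.9) falls in the 200-600 ms range; see
#: scripts/calibrate_stimulus.py for the procedure.
DEFAULT_RATE_INCREMENT = 140.0


def _default_conductances() -> ConductanceTable:
    """Per-synapse conductance table used for simulations.

    The quoted pyramidal recurrent-AMPA value of 0.5 nS is read as a
    misprint for 0.05 nS: with 0.5 nS the fast excitatory feedback exceeds
    what the interneuron population (recruited at 0.04 nS) can balance and
    every cell locks at its refractory-limited rate, independent of w_plus.
    """
    return ConductanceTable(
        pyramidal=ConductanceRow(g_ext_AMPA=2.1, g_rec_AMPA=0.05, g_NMDA=0.165, g_GABA=1.3),
        interneuron=ConductanceRow(g_ext_AMPA=1.62, g_rec_AMPA=0.04, g_NMDA=0.13, g_GABA=1.0),
    )


@dataclass(frozen=True)
class StimulusProtocol:
    """Timed selective increment to the external Poisson rate.

    ``target`` is "A", "B", or "both".  With target "both", ``coherence``
    (percent) splits the increment asymmetrically:
    group A receives ``rate_increment * (1 + c/100) / 2`` and group B
    ``rate_increment * (1 - c/100) / 2``.
    """

    onset: float = 500.0          # ms
    duration: float = 1000.0      # ms
    target: str = "A"
    rate_increment: float = DEFAULT_RATE_INCREMENT  # Hz per stimulated cell
    coherence: float | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rate_increment < 0:
            raise ValueError("rate_increment must be nonnegative")
        if self.target not in ("A", "B", "both"):
            raise ValueError(f"target must be 'A', 'B' or 'both', got {self.target!r}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def group_increments(self) -> tuple[float, float]:
        """(Hz added to group A, Hz added to group B) during the window."""
        if self.target == "A":
            return self.rate_increment, 0.0
        if self.target == "B":
            return 0.0, self.rate_increment
        c = 0.0 if self.coherence is None else self.coherence
        return (self.rate_increment * (1 + c / 100.0) / 2.0,
                self.rate_increment * (1 - c / 100.0) / 2.0)


@dataclass(frozen=True)
class TrialConfig:
    """Complete description of one simulated trial."""

    total_duration: float = 3000.0   # ms
    dt: float = 0.02                 # ms
    background_rate: float = 2400.0  # Hz external Poisson rate per cell
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)
    N: int = 480
    group_size: int = 96
    w_plus: float = 1.9
    V_L: float = -70.0               # resting potential under study (mV)
    rmp_pyramidal_only: bool = False  # if True, V_L applies to pyramidal cells only
    pyramidal: NeuronParams = field(default_factory=lambda: PYRAMIDAL)
    interneuron: NeuronParams = field(default_factory=lambda: INTERNEURON)
    synapses: SynapseParams = field(default_factory=lambda: DEFAULT_SYNAPSES)
    conductances: ConductanceTable = field(default_factory=_default_conductances)
    #: Multiplier on the recurrent conductances (g_rec_AMPA, g_NMDA, g_GABA);
    #: None selects the size compensation REFERENCE_SIZE / N.
    recurrent_scale: float | None = None
    rt_threshold: float = analysis.RT_THRESHOLD
    persistence_rate: float = analysis.PERSISTENCE_RATE
    persistence_window: float = analysis.PERSISTENCE_WINDOW
    rate_window: float = analysis.RATE_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if self.total_duration < self.stimulus.offset:
            raise ValueError("total_duration must cover the stimulus window")

    def effective_neuron_params(self) -> tuple[NeuronParams, NeuronParams]:
        """Per-class parameters with the studied resting potential applied."""
        pyr = self.pyramidal.with_resting_potential(self.V_L)
        inh = (self.interneuron if self.rmp_pyramidal_only
               else self.interneuron.with_resting_potential(self.V_L))
        return pyr, inh

    def digest(self) -> str:
        """Stable hash of every parameter that affects the simulation."""
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
            return o
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effective_conductances(self) -> tuple[ConductanceRow, ConductanceRow]:
        """Conductance rows with the network-size compensation applied."""
        scale = self.recurrent_scale if self.recurrent_scale is not None else REFERENCE_SIZE / self.N
        return (self.conductances.pyramidal.scaled(g_rec_AMPA=scale, g_NMDA=scale, g_GABA=scale),
                self.conductances.interneuron.scaled(g_rec_AMPA=scale, g_NMDA=scale, g_GABA=scale))


@dataclass
class TrialResult:
    """Outcome of one trial."""

    spike_times: np.ndarray   # ms
    spike_ids: np.ndarray
    traces: dict              # population label -> analysis.RateTrace
    reaction_time: float | None
    winner: str | None        # "A", "B", or None
    persistent: bool
    seed: int
    config_digest: str

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def external_event_counts(neuron_rates: np.ndarray, n_steps: int, dt: float,
                          rng: np.random.Generator,
                          stim_window: tuple[int, int] | None = None,
                          stim_rates: np.ndarray | None = None) -> np.ndarray:
    """Per-step external spike counts for every neuron.

    Counts are Poisson(rate * dt) per step (rate * dt is ~0.05 at the
    default background, so Bernoulli sampling would undercount).  Rates are
    in Hz; during the stimulus step window ``stim_rates`` replaces
    ``neuron_rates``.  Used by the reference stepper and in statistical
    tests; the compiled kernel draws the same law by pool superposition.
    """
    lam = neuron_rates * dt * 1e-3
    out = rng.poisson(lam=lam, size=(n_steps, neuron_rates.size))
    if stim_window is not None and stim_rates is not None:
        a, b = stim_window
        out[a:b] = rng.poisson(lam=stim_rates * dt * 1e-3, size=(b - a, neuron_rates.size))
    return out.astype(np.int64)


def _winner_and_rt(trace_a, trace_b, onset, threshold):
    """First selective group to cross the rate threshold after onset.

    Ties at the same window are broken toward the higher rate, then toward A.
    """
    rt_a = analysis.reaction_time(trace_a, threshold, onset)
    rt_b = analysis.reaction_time(trace_b, threshold, onset)
    if rt_a is None and rt_b is None:
        return None, None
    if rt_b is None or (rt_a is not None and rt_a < rt_b):
        return "A", rt_a
    if rt_a is None or rt_b < rt_a:
        return "B", rt_b
    ia = np.searchsorted(trace_a.centers, onset + rt_a)
    if trace_a.rates[ia] >= trace_b.rates[ia]:
        return "A", rt_a
    return "B", rt_b


def run_trial(cfg: TrialConfig) -> TrialResult:
    """Simulate one full trial and score it.

    Deterministic: identical config (including seed) gives an identical
    spike raster.  Raises RuntimeError if the state goes non-finite.
    """
    spec, _ = build_network(cfg.N, cfg.group_size, cfg.w_plus)
    pyr, inh = cfg.effective_neuron_params()
    syn = cfg.synapses
    cp, ci = cfg.effective_conductances()
    dt = cfg.dt
    n_steps = int(round(cfg.total_duration / dt))
    inc_a, inc_b = cfg.stimulus.group_increments()
    stim_start = int(round(cfg.stimulus.onset / dt))
    stim_end = int(round(cfg.stimulus.offset / dt))
    max_spikes = int(cfg.N * cfg.total_duration * 1e-3 * 400) + 10_000  # 400 Hz/cell headroom

    spike_steps, spike_ids, n_spk, status, _, _ = _kernel.run_network(
        n_steps, dt,
        spec.N_E, spec.N_I, spec.group_size,
        spec.w_plus, spec.w_minus,
        np.array([pyr.V_L, inh.V_L]), np.array([pyr.V_th, inh.V_th]),
        np.array([pyr.V_reset, inh.V_reset]), np.array([pyr.C_m, inh.C_m]),
        np.array([pyr.g_L, inh.g_L]),
        np.array([round(pyr.tau_ref / dt), round(inh.tau_ref / dt)], dtype=np.int64),
        syn.tau_AMPA, syn.tau_NMDA_decay, syn.tau_NMDA_rise, syn.alpha,
        syn.tau_GABA, syn.latency_steps(dt), syn.Mg, syn.V_E, syn.V_I,
        np.array([cp.g_ext_AMPA, ci.g_ext_AMPA]), np.array([cp.g_rec_AMPA, ci.g_rec_AMPA]),
        np.array([cp.g_NMDA, ci.g_NMDA]), np.array([cp.g_GABA, ci.g_GABA]),
        cfg.background_rate * dt * 1e-3, inc_a * dt * 1e-3, inc_b * dt * 1e-3,
        stim_start, stim_end,
        cfg.seed,
        np.zeros((0, 0), dtype=np.int64), 0,
        max_spikes,
    )
    if status == _kernel.STATUS_NONFINITE:
        raise RuntimeError(f"simulation diverged (non-finite state), config {cfg.digest()}")
    if status == _kernel.STATUS_OVERFLOW:
        raise RuntimeError("spike record overflow; raise max_spikes headroom")
    times = (spike_steps[:n_spk] + 1) * dt
    ids = spike_ids[:n_spk].copy()

    traces = {}
    for label, code in (("A", GROUP_A), ("B", GROUP_B),
                        ("nonselective", GROUP_NONSELECTIVE), ("inhibitory", GROUP_INHIBITORY)):
        traces[label] = analysis.population_rate(
            times, ids, spec.members(code), cfg.total_duration, cfg.rate_window)

    winner, rt = _winner_and_rt(traces["A"], traces["B"],
                                cfg.stimulus.onset, cfg.rt_threshold)
    persistent = False
    if winner is not None:
        persistent = analysis.detect_persistence(
            traces[winner], cfg.stimulus.offset,
            cfg.persistence_window, cfg.persistence_rate)
    return TrialResult(spike_times=times, spike_ids=ids, traces=traces,
                       reaction_time=rt, winner=winner, persistent=persistent,
                       seed=cfg.seed, config_digest=cfg.digest())


def derive_seed(base_seed: int, V_L: float, w_plus: float, trial: int) -> int:
    """Stable per-trial seed, independent of grid shape or cell order."""
    key = f"{base_seed}|{V_L:.6g}|{w_plus:.6g}|{trial}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def run_sweep(grid, trials_per_cell: int, base_cfg: TrialConfig,
              progress: bool = False) -> analysis.SweepResult:
    """Run ``trials_per_cell`` trials at every (V_L, w_plus) grid cell.

    ``grid`` is an iterable of (V_L, w_plus) pairs.  Reaction times of
    non-deciding trials are recorded as None; a cell is flagged no-decision
    only when no trial crossed the rate threshold.
    """
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be at least 1")
    grid = list(grid)
    cells = []
    for (v_l, w_plus) in grid:
        rts, persists, seeds = [], [], []
        for k in range(trials_per_cell):
            seed = derive_seed(base_cfg.seed, v_l, w_plus, k)
            cfg = replace(base_cfg, V_L=v_l, w_plus=w_plus, seed=seed)
            res = run_trial(cfg)
            rts.append(res.reaction_time)
            persists.append(res.persistent)
            seeds.append(seed)
            if progress:
                print(f"  V_L={v_l:+.1f} w+={w_plus:.2f} trial {k}: "
                      f"RT={res.reaction_time} winner={res.winner}", flush=True)
        cells.append(analysis.CellResult(V_L=v_l, w_plus=w_plus, reaction_times=rts,
                                         persistent=persists, seeds=seeds))
    v_vals = sorted({v for v, _ in grid})
    w_vals = sorted({w for _, w in grid})
    return analysis.SweepResult(V_L_values=v_vals, w_plus_values=w_vals, cells=cells)
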