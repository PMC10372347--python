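"""Neuron and synapse dynamics with a fixed-step second-order (Heun) integrator.

This module is the readable reference implementation of the model equations.
Full trials run through the compiled kernel in :mod:`wtanet._kernel`, which
implements the identical update scheme; agreement between the two is checked
in the test suite.

Membrane equation (leaky integrate-and-fire, subthreshold):

    C_m dV/dt = -g_L (V - V_L) - I_syn(t)

with the total synaptic current decomposed as

    I_syn = I_ext,AMPA + I_rec,AMPA + I_rec,NMDA + I_rec,GABA

Each current is ``g * (V - V_rev) * <gating>``; with this sign convention a
positive I_syn is subtracted from the membrane equation, so excitatory
currents (V below V_E = 0) come out negative and depolarize.

Update order within one step (dt): deliver delayed spikes as +1 gating
increments -> advance gating and membranes by one Heun step -> apply
threshold/reset and enqueue emitted spikes for delivery ``latency`` later.
Refractory neurons are clamped at V_reset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConductanceRow, NeuronParams, SynapseParams

__all__ = [
    "mg_block_factor",
    "synaptic_current",
    "GatingState",
    "step_gating",
    "step_membrane",
    "DelayBuffer",
    "ReferenceNetwork",
]


def mg_block_factor(V, Mg: float):
    """Voltage-dependent magnesium attenuation of the NMDA conductance.

    Returns ``1 / (1 + Mg * exp(-0.062 V) / 3.57)``, a factor in (0, 1]
    that increases with depolarization and equals 1 when Mg = 0.

    Parameters
    ----------
    V : float or ndarray
        Membrane potential in mV.
    Mg : float
        Extracellular magnesium concentration in mM (>= 0).
    """
    if Mg < 0:
        raise ValueError("Mg must be nonnegative")
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * np.asarray(V, dtype=float)) / 3.57)


@dataclass
class GatingState:
    """Per-source synaptic gating variables.

    ``s_ext`` is indexed by *postsynaptic* neuron (each cell has its own
    external Poisson train); the recurrent variables are indexed by
    *presynaptic* neuron and shared by every target, since the weight is
    the only pair-specific factor.
    """

    s_ext: np.ndarray     # (N,) external AMPA gating per target neuron
    s_ampa: np.ndarray    # (NE,) recurrent AMPA gating per excitatory source
    x_nmda: np.ndarray    # (NE,) NMDA rise variable per excitatory source
    s_nmda: np.ndarray    # (NE,) NMDA gating per excitatory source, in [0, 1]
    s_gaba: np.ndarray    # (NI,) GABA gating per interneuron source

    @classmethod
    def zeros(cls, n_total: int, n_exc: int, n_inh: int) -> "GatingState":
        return cls(
            s_ext=np.zeros(n_total),
            s_ampa=np.zeros(n_exc),
            x_nmda=np.zeros(n_exc),
            s_nmda=np.zeros(n_exc),
            s_gaba=np.zeros(n_inh),
        )

    def copy(self) -> "GatingState":
        return GatingState(self.s_ext.copy(), self.s_ampa.copy(),
                           self.x_nmda.copy(), self.s_nmda.copy(), self.s_gaba.copy())


def _gating_derivs(g: GatingState, syn: SynapseParams):
    """Time derivatives of the continuous part of the gating ODEs."""
    ds_ext = -g.s_ext / syn.tau_AMPA
    ds_ampa = -g.s_ampa / syn.tau_AMPA
    dx = -g.x_nmda / syn.tau_NMDA_rise
    ds_nmda = -g.s_nmda / syn.tau_NMDA_decay + syn.alpha * g.x_nmda * (1.0 - g.s_nmda)
    ds_gaba = -g.s_gaba / syn.tau_GABA
    return ds_ext, ds_ampa, dx, ds_nmda, ds_gaba


def step_gating(gating: GatingState, dt: float, syn: SynapseParams,
                ext_spikes: np.ndarray | None = None,
                exc_spikes: np.ndarray | None = None,
                inh_spikes: np.ndarray | None = None) -> GatingState:
    """Advance all gating variables by one step.

    Delivered spikes (counts per source, may exceed 1) are applied as
    discrete +1 increments at the start of the step; the continuous decay /
    rise dynamics are then advanced with one Heun step.  ``s_nmda`` is
    clamped to [0, 1] to remove any second-order overshoot of its invariant
    bound.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = gating.copy()
    if ext_spikes is not None:
        g.s_ext += ext_spikes
    if exc_spikes is not None:
        g.s_ampa += exc_spikes
        g.x_nmda += exc_spikes
    if inh_spikes is not None:
        g.s_gaba += inh_spikes

    k1 = _gating_derivs(g, syn)
    g2 = GatingState(*(y + dt * k for y, k in zip(
        (g.s_ext, g.s_ampa, g.x_nmda, g.s_nmda, g.s_gaba), k1)))
    k2 = _gating_derivs(g2, syn)
    out = GatingState(*(y + 0.5 * dt * (a + b) for y, a, b in zip(
        (g.s_ext, g.s_ampa, g.x_nmda, g.s_nmda, g.s_gaba), k1, k2)))
    np.clip(out.s_nmda, 0.0, 1.0, out=out.s_nmda)
    return out


def synaptic_current(V: float, gating: GatingState, cond: ConductanceRow,
                     weights: np.ndarray, syn: SynapseParams,
                     s_ext: float | None = None) -> float:
    """Total synaptic current (pA) onto one target neuron.

    Parameters
    ----------
    V : float
        Target membrane potential (mV).
    gating : GatingState
        Presynaptic gating variables.
    cond : ConductanceRow
        Conductances for the target's cell class.
    weights : ndarray
        Recurrent excitatory weight row w_j for this target (length NE).
        Applied to both the recurrent AMPA and NMDA sums; GABA is unweighted.
    s_ext : float, optional
        The target's own external gating value; defaults to ``gating.s_ext``
        summed, which is only correct for a single-neuron gating state.
    """
    if weights.shape != gating.s_ampa.shape:
        raise ValueError(
            f"weight row shape {weights.shape} does not match excitatory gating {gating.s_ampa.shape}")
    if s_ext is None:
        s_ext = float(np.sum(gating.s_ext))
    i_ext = cond.g_ext_AMPA * (V - syn.V_E) * s_ext
    i_ampa = cond.g_rec_AMPA * (V - syn.V_E) * float(weights @ gating.s_ampa)
    i_nmda = (cond.g_NMDA * (V - syn.V_E) * float(mg_block_factor(V, syn.Mg))
              * float(weights @ gating.s_nmda))
    i_gaba = cond.g_GABA * (V - syn.V_I) * float(np.sum(gating.s_gaba))
    return i_ext + i_ampa + i_nmda + i_gaba


def step_membrane(V: float, Isyn: float, p: NeuronParams,
                  refractory_remaining: float, dt: float):
    """One Heun step of the membrane equation with current held constant.

    Returns ``(V', spiked, refractory_remaining')``.  While refractory the
    potential stays clamped at V_reset.  On crossing threshold the neuron
    spikes, resets, and restarts its refractory timer.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if refractory_remaining > 0:
        return p.V_reset, False, max(refractory_remaining - dt, 0.0)
    k1 = (-p.g_L * (V - p.V_L) - Isyn) / p.C_m
    v2 = V + dt * k1
    k2 = (-p.g_L * (v2 - p.V_L) - Isyn) / p.C_m
    v_new = V + 0.5 * dt * (k1 + k2)
    if v_new >= p.V_th:
        return p.V_reset, True, p.tau_ref
    return v_new, False, 0.0


class DelayBuffer:
    """Ring buffer of pending spike deliveries (uniform latency).

    Every emitted spike is delivered exactly once, exactly
    ``latency / dt`` steps after emission.
    """

    def __init__(self, delay_steps: int, n_neurons: int):
        if delay_steps < 1:
            raise ValueError("delay must be at least one step")
        self.delay_steps = delay_steps
        self._buf = np.zeros((delay_steps, n_neurons), dtype=np.int64)
        self._pos = 0

    def push(self, neuron_ids: np.ndarray) -> None:
        """Schedule spikes emitted this step for delivery ``delay_steps`` later."""
        slot = (self._pos + self.delay_steps - 1) % self.delay_steps
        np.add.at(self._buf[slot], neuron_ids, 1)

    def pop_due(self) -> np.ndarray:
        """Return and clear the spike counts due for delivery this step."""
        due = self._buf[self._pos].copy()
        self._buf[self._pos] = 0
        self._pos = (self._pos + 1) % self.delay_steps
        return due


class ReferenceNetwork:
    """Dense-weight NumPy implementation of the full network update.

    Slow but transparent; used to validate the compiled kernel and for
    small hand-checkable scenarios.  ``weights`` is the (N, NE) matrix of
    recurrent excitatory weights per target (interneuron rows are all 1,
    pyramidal diagonal is 0 — no self-connections).
    """

    def __init__(self, weights: np.ndarray, n_exc: int,
                 pyr: NeuronParams, inh: NeuronParams,
                 cond_pyr: ConductanceRow, cond_inh: ConductanceRow,
                 syn: SynapseParams, dt: float):
        self.N = weights.shape[0]
        self.NE = n_exc
        self.NI = self.N - n_exc
        if weights.shape[1] != n_exc:
            raise ValueError("weight matrix must have one column per excitatory source")
        self.W = np.asarray(weights, dtype=float)
        self.pyr, self.inh, self.syn, self.dt = pyr, inh, syn, dt
        self.is_exc = np.arange(self.N) < n_exc
        self.V = np.where(self.is_exc, pyr.V_L, inh.V_L).astype(float)
        self.refr_steps = np.zeros(self.N, dtype=np.int64)
        self.ref_steps_by_class = np.where(self.is_exc,
                                           round(pyr.tau_ref / dt), round(inh.tau_ref / dt))
        self.gating = GatingState.zeros(self.N, self.NE, self.NI)
        self.delay = DelayBuffer(syn.latency_steps(dt), self.N)
        self.g_ext = np.where(self.is_exc, cond_pyr.g_ext_AMPA, cond_inh.g_ext_AMPA)
        self.g_rec = np.where(self.is_exc, cond_pyr.g_rec_AMPA, cond_inh.g_rec_AMPA)
        self.g_nmda = np.where(self.is_exc, cond_pyr.g_NMDA, cond_inh.g_NMDA)
        self.g_gaba = np.where(self.is_exc, cond_pyr.g_GABA, cond_inh.g_GABA)
        self.V_L = np.where(self.is_exc, pyr.V_L, inh.V_L)
        self.g_L = np.where(self.is_exc, pyr.g_L, inh.g_L)
        self.C_m = np.where(self.is_exc, pyr.C_m, inh.C_m)
        self.step_index = 0
        self.spike_times: list[float] = []
        self.spike_ids: list[int] = []

    def _currents(self, V: np.ndarray, g: GatingState) -> np.ndarray:
        syn = self.syn
        wsum_ampa = self.W @ g.s_ampa
        wsum_nmda = self.W @ g.s_nmda
        gaba_total = np.sum(g.s_gaba)
        # no self-connections: interneurons do not see their own GABA gating
        gaba_sum = np.full(self.N, gaba_total)
        gaba_sum[self.NE:] -= g.s_gaba
        i = self.g_ext * (V - syn.V_E) * g.s_ext
        i += self.g_rec * (V - syn.V_E) * wsum_ampa
        i += self.g_nmda * (V - syn.V_E) * mg_block_factor(V, syn.Mg) * wsum_nmda
        i += self.g_gaba * (V - syn.V_I) * gaba_sum
        return i

    def step(self, external_counts: np.ndarray) -> np.ndarray:
        """Advance the network by dt; returns the ids of neurons spiking this step."""
        if external_counts.shape != (self.N,):
            raise ValueError("external_counts must have one entry per neuron")
        dt, syn = self.dt, self.syn
        g = self.gating
        # 1. deliver: delayed recurrent spikes and this step's external events
        due = self.delay.pop_due()
        g.s_ext += external_counts
        g.s_ampa += due[:self.NE]
        g.x_nmda += due[:self.NE]
        g.s_gaba += due[self.NE:]
        # 2. Heun step of the coupled gating + membrane system
        k1g = _gating_derivs(g, syn)
        g2 = GatingState(*(y + dt * k for y, k in zip(
            (g.s_ext, g.s_ampa, g.x_nmda, g.s_nmda, g.s_gaba), k1g)))
        active = self.refr_steps <= 0
        k1v = (-self.g_L * (self.V - self.V_L) - self._currents(self.V, g)) / self.C_m
        V2 = self.V + dt * k1v
        k2v = (-self.g_L * (V2 - self.V_L) - self._currents(V2, g2)) / self.C_m
        V_reset = np.where(self.is_exc, self.pyr.V_reset, self.inh.V_reset)
        V_new = np.where(active, self.V + 0.5 * dt * (k1v + k2v), V_reset)
        k2g = _gating_derivs(g2, syn)
        self.gating = GatingState(*(y + 0.5 * dt * (a + b) for y, a, b in zip(
            (g.s_ext, g.s_ampa, g.x_nmda, g.s_nmda, g.s_gaba), k1g, k2g)))
        np.clip(self.gating.s_nmda, 0.0, 1.0, out=self.gating.s_nmda)
        self.refr_steps = np.maximum(self.refr_steps - 1, 0)
        # 3. threshold, reset, enqueue
        spiked = active & (V_new >= np.where(self.is_exc, self.pyr.V_th, self.inh.V_th))
        V_new = np.where(spiked, V_reset, V_new)
        self.refr_steps = np.where(spiked, self.ref_steps_by_class, self.refr_steps)
        self.V = V_new
        ids = np.nonzero(spiked)[0]
        if ids.size:
            self.delay.push(ids)
            t = (self.step_index + 1) * dt
            self.spike_times.extend([t] * ids.size)
            self.spike_ids.extend(ids.tolist())
        self.step_index += 1
        return ids
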