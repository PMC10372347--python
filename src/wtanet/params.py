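"""Physiological parameter sets for the spiking network.

All quantities use the closed unit system {mV, ms, nS, pF, pA}:
``pF * mV / ms`` and ``nS * mV`` are both pA, so no conversion factors
appear in the integration loop.  Firing rates in user-facing configs are
given in Hz and converted to events/ms internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire cell constants.

    Attributes
    ----------
    V_L : float
        Leak (resting) potential in mV.  This is the quantity swept when
        the resting membrane potential of a population is manipulated.
    V_th : float
        Firing threshold in mV.
    V_reset : float
        Post-spike reset potential in mV.
    C_m : float
        Membrane capacitance in pF.
    g_L : float
        Leak conductance in nS.
    tau_ref : float
        Absolute refractory period in ms; the membrane is clamped at
        ``V_reset`` for this long after each spike.
    """

    V_L: float = -70.0
    V_th: float = -50.0
    V_reset: float = -60.0
    C_m: float = 500.0
    g_L: float = 25.0
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_th:
            raise ValueError(f"V_reset ({self.V_reset}) must be below V_th ({self.V_th})")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be nonnegative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L in ms."""
        return self.C_m / self.g_L

    @property
    def rheobase(self) -> float:
        """Minimal sustained current (pA) that reaches threshold: g_L * (V_th - V_L)."""
        return self.g_L * (self.V_th - self.V_L)

    def with_resting_potential(self, V_L: float) -> "NeuronParams":
        return replace(self, V_L=V_L)


#: Default pyramidal-cell constants (tau_m = 20 ms, rheobase 500 pA).
PYRAMIDAL = NeuronParams(V_L=-70.0, V_th=-50.0, V_reset=-60.0, C_m=500.0, g_L=25.0, tau_ref=2.0)

#: Default fast-spiking interneuron constants (tau_m = 10 ms).
INTERNEURON = NeuronParams(V_L=-70.0, V_th=-50.0, V_reset=-60.0, C_m=200.0, g_L=20.0, tau_ref=1.0)


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics shared by every synapse class in the model.

    AMPA and GABA channels are single-exponential: each presynaptic spike
    increments the gating variable by 1 and it decays with ``tau_AMPA`` /
    ``tau_GABA``.  NMDA channels use a two-variable scheme: spikes drive a
    fast rise variable x (decay ``tau_NMDA_rise``) which opens the gating
    variable through ds/dt = -s/tau_decay + alpha * x * (1 - s), so s
    saturates at 1 under sustained drive.  The NMDA current is further
    attenuated by the voltage-dependent magnesium block
    1 / (1 + Mg * exp(-0.062 V) / 3.57).
    """

    tau_AMPA: float = 2.0            # ms
    tau_NMDA_decay: float = 100.0    # ms
    tau_NMDA_rise: float = 2.0       # ms
    alpha: float = 0.5               # 1/ms, NMDA gating gain
    tau_GABA: float = 5.0            # ms
    latency: float = 5.0             # ms, spike delivery delay (all synapses)
    Mg: float = 1.0                  # mM extracellular magnesium
    V_E: float = 0.0                 # mV excitatory reversal
    V_I: float = -70.0               # mV inhibitory reversal

    def __post_init__(self) -> None:
        for name in ("tau_AMPA", "tau_NMDA_decay", "tau_NMDA_rise", "tau_GABA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.latency < 0:
            raise ValueError("latency must be nonnegative")
        if self.Mg < 0:
            raise ValueError("Mg concentration must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def latency_steps(self, dt: float) -> int:
        """Delivery delay in integration steps; latency must be a multiple of dt."""
        n = round(self.latency / dt)
        if abs(n * dt - self.latency) > 1e-9:
            raise ValueError(f"latency {self.latency} ms is not an integer multiple of dt {dt} ms")
        return n


DEFAULT_SYNAPSES = SynapseParams()


@dataclass(frozen=True)
class ConductanceRow:
    """Peak synaptic conductances (nS) onto one target cell class."""

    g_ext_AMPA: float
    g_rec_AMPA: float
    g_NMDA: float
    g_GABA: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")

    def scaled(self, g_ext_AMPA: float = 1.0, g_rec_AMPA: float = 1.0,
               g_NMDA: float = 1.0, g_GABA: float = 1.0) -> "ConductanceRow":
        """Return a copy with per-class multiplicative scale factors applied."""
        return ConductanceRow(
            g_ext_AMPA=self.g_ext_AMPA * g_ext_AMPA,
            g_rec_AMPA=self.g_rec_AMPA * g_rec_AMPA,
            g_NMDA=self.g_NMDA * g_NMDA,
            g_GABA=self.g_GABA * g_GABA,
        )


@dataclass(frozen=True)
class ConductanceTable:
    """Synaptic conductances per target class."""

    pyramidal: ConductanceRow = field(
        default_factory=lambda: ConductanceRow(g_ext_AMPA=2.1, g_rec_AMPA=0.5, g_NMDA=0.165, g_GABA=1.3)
    )
    interneuron: ConductanceRow = field(
        default_factory=lambda: ConductanceRow(g_ext_AMPA=1.62, g_rec_AMPA=0.04, g_NMDA=0.13, g_GABA=1.0)
    )

    def row(self, cell_class: str) -> ConductanceRow:
        if cell_class == "pyramidal":
            return self.pyramidal
        if cell_class == "interneuron":
            return self.interneuron
        raise ValueError(f"unknown cell class {cell_class!r}; expected 'pyramidal' or 'interneuron'")


DEFAULT_CONDUCTANCES = ConductanceTable()
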