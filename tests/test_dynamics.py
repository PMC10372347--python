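"""Unit tests of the neuron/synapse equations and the Heun integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtanet import (GatingState, INTERNEURON, PYRAMIDAL, SynapseParams,
                    mg_block_factor, step_gating, step_membrane)
from wtanet.dynamics import synaptic_current
from wtanet.params import ConductanceRow

SYN = SynapseParams()


class TestMgBlock:
    def test_zero_magnesium_removes_block(self):
        for v in (-90.0, -70.0, 0.0, 40.0):
            assert mg_block_factor(v, 0.0) == 1.0

    @pytest.mark.parametrize("v, mg, expected", [
        (0.0, 1.0, 0.781182),    # 1 / (1 + 1/3.57)
        (-70.0, 1.0, 0.044471),  # 1 / (1 + e^{4.34}/3.57)
    ])
    def test_point_values(self, v, mg, expected):
        assert mg_block_factor(v, mg) == pytest.approx(expected, abs=1e-5)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=-120, max_value=60), min_size=2, max_size=20),
           st.floats(min_value=0.0, max_value=12.0))
    def test_monotone_in_voltage(self, vs, mg):
        vs = np.sort(np.asarray(vs))
        f = mg_block_factor(vs, mg)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f > 0) & (f <= 1))

    def test_negative_magnesium_rejected(self):
        with pytest.raises(ValueError):
            mg_block_factor(-70.0, -1.0)


class TestGating:
    def _empty(self, n=1):
        return GatingState.zeros(n, n, n)

    @pytest.mark.parametrize("attr, tau", [("s_ampa", 2.0), ("s_gaba", 5.0)])
    def test_exponential_decay_closed_form(self, attr, tau):
        g = self._empty()
        getattr(g, attr)[0] = 1.0
        dt = 0.02
        for _ in range(int(tau / dt)):
            g = step_gating(g, dt, SYN)
        assert getattr(g, attr)[0] == pytest.approx(np.exp(-1.0), abs=1e-5)

    def test_spike_increments_by_one(self):
        g = self._empty()
        g = step_gating(g, 0.02, SYN, exc_spikes=np.array([2.0]))
        # two delivered spikes -> +2 before decay within the step
        assert g.s_ampa[0] == pytest.approx(2.0 * np.exp(-0.02 / 2.0), rel=1e-4)
        assert g.x_nmda[0] == pytest.approx(2.0 * np.exp(-0.02 / 2.0), rel=1e-4)

    def test_nmda_fixed_point_under_clamped_rise(self):
        # with x held at 1, s* = alpha*tau_decay / (1 + alpha*tau_decay) = 50/51
        g = self._empty()
        dt = 0.02
        for _ in range(50_000):  # 1 s = 10 tau_decay
            g.x_nmda[0] = 1.0
            g = step_gating(g, dt, SYN)
        assert g.s_nmda[0] == pytest.approx(50.0 / 51.0, abs=1e-4)

    def test_nmda_stays_in_unit_interval_under_bursts(self):
        g = self._empty()
        rng = np.random.default_rng(7)
        for _ in range(5000):
            spikes = np.array([float(rng.poisson(0.5))])
            g = step_gating(g, 0.02, SYN, exc_spikes=spikes)
            assert 0.0 <= g.s_nmda[0] <= 1.0
            assert g.s_ampa[0] >= 0 and g.x_nmda[0] >= 0

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            step_gating(self._empty(), 0.0, SYN)


class TestMembrane:
    def test_resting_potential_is_fixed_point(self):
        v, spiked, _ = step_membrane(PYRAMIDAL.V_L, 0.0, PYRAMIDAL, 0.0, 0.02)
        assert v == PYRAMIDAL.V_L and not spiked

    @pytest.mark.parametrize("p", [PYRAMIDAL, INTERNEURON], ids=["pyr", "int"])
    def test_relaxation_matches_closed_form(self, p):
        # V(t) = V_L + (V0 - V_L) exp(-t/tau_m), checked over 100 ms
        dt, v0 = 0.02, -60.0
        v, refr = v0, 0.0
        for k in range(int(100.0 / dt)):
            v, _, refr = step_membrane(v, 0.0, p, refr, dt)
            t = (k + 1) * dt
            expected = p.V_L + (v0 - p.V_L) * np.exp(-t / p.tau_m)
            assert abs(v - expected) < 1e-3

    def test_rheobase_separates_spiking_from_silence(self):
        # rheobase = g_L (V_th - V_L) = 500 pA for the pyramidal cell
        assert PYRAMIDAL.rheobase == pytest.approx(500.0)

        def spikes_within(i_syn, t_max=2000.0):
            v, refr = PYRAMIDAL.V_L, 0.0
            for _ in range(int(t_max / 0.02)):
                v, spiked, refr = step_membrane(v, i_syn, PYRAMIDAL, refr, 0.02)
                if spiked:
                    return True
            return False

        assert spikes_within(-510.0)          # just above rheobase (depolarizing sign)
        assert not spikes_within(-490.0)      # just below: approaches threshold, never crosses

    def test_refractory_clamps_at_reset(self):
        v, spiked, refr = step_membrane(-55.0, -2000.0, PYRAMIDAL, 1.5, 0.02)
        assert v == PYRAMIDAL.V_reset and not spiked and refr == pytest.approx(1.48)


class TestSynapticCurrent:
    COND = ConductanceRow(g_ext_AMPA=2.1, g_rec_AMPA=0.5, g_NMDA=0.165, g_GABA=1.3)

    def test_all_gating_zero_gives_zero(self):
        g = GatingState.zeros(1, 3, 2)
        w = np.ones(3)
        assert synaptic_current(-60.0, g, self.COND, w, SYN, s_ext=0.0) == 0.0

    def test_gaba_vanishes_at_inhibitory_reversal(self):
        g = GatingState.zeros(1, 3, 2)
        g.s_gaba[:] = 1.0
        assert synaptic_current(SYN.V_I, g, self.COND, np.ones(3), SYN, s_ext=0.0) == 0.0

    def test_single_external_term(self):
        # g_ext * (V - V_E) * s = 2.1 * (-60) * 1 = -126 pA (depolarizing)
        g = GatingState.zeros(1, 3, 2)
        val = synaptic_current(-60.0, g, self.COND, np.ones(3), SYN, s_ext=1.0)
        assert val == pytest.approx(-126.0)

    def test_dimension_mismatch_raises(self):
        g = GatingState.zeros(1, 3, 2)
        with pytest.raises(ValueError):
            synaptic_current(-60.0, g, self.COND, np.ones(4), SYN, s_ext=0.0)
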