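"""Tests of external drive statistics, trial orchestration, and sweeps."""

import numpy as np
import pytest
from dataclasses import replace

from wtanet import StimulusProtocol, TrialConfig, derive_seed, run_sweep, run_trial
from wtanet.protocol import external_event_counts


class TestExternalEvents:
    def test_poisson_mean_matches_rate(self, rng):
        # 2.4 kHz for 1 s: empirical count within 3 sigma of 2400
        counts = external_event_counts(np.array([2400.0]), 50_000, 0.02, rng)
        total = counts.sum()
        assert abs(total - 2400) < 3 * np.sqrt(2400)

    def test_zero_rate_is_silent(self, rng):
        counts = external_event_counts(np.array([0.0, 0.0]), 1000, 0.02, rng)
        assert counts.sum() == 0

    def test_stimulus_window_only_changes_targeted_rates(self, rng):
        rates = np.array([1000.0, 1000.0])
        stim = np.array([5000.0, 1000.0])  # neuron 0 stimulated, neuron 1 not
        counts = external_event_counts(rates, 20_000, 0.02, rng,
                                       stim_window=(5000, 15_000), stim_rates=stim)
        outside = counts[:5000].sum(axis=0) + counts[15_000:].sum(axis=0)
        inside = counts[5000:15_000].sum(axis=0)
        # 200 ms windows: expectations 200/1000 counts
        assert abs(inside[0] - 1000) < 4 * np.sqrt(1000)
        assert abs(inside[1] - 200) < 4 * np.sqrt(200)
        assert abs(outside[0] - 200) < 4 * np.sqrt(200)


class TestStimulusProtocol:
    def test_single_sided_increments(self):
        s = StimulusProtocol(target="A", rate_increment=100.0)
        assert s.group_increments() == (100.0, 0.0)
        s = StimulusProtocol(target="B", rate_increment=100.0)
        assert s.group_increments() == (0.0, 100.0)

    def test_coherence_splits_two_sided_input(self):
        s = StimulusProtocol(target="both", rate_increment=100.0, coherence=20.0)
        a, b = s.group_increments()
        assert a == pytest.approx(60.0) and b == pytest.approx(40.0)
        assert a + b == pytest.approx(100.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(duration=0.0)
        with pytest.raises(ValueError):
            StimulusProtocol(target="C")
        with pytest.raises(ValueError):
            StimulusProtocol(rate_increment=-1.0)


class TestTrialConfig:
    def test_stimulus_must_fit_in_trial(self):
        with pytest.raises(ValueError):
            TrialConfig(total_duration=1000.0,
                        stimulus=StimulusProtocol(onset=500.0, duration=1000.0))

    def test_resting_potential_applies_to_both_classes_by_default(self):
        cfg = TrialConfig(V_L=-75.0)
        pyr, inh = cfg.effective_neuron_params()
        assert pyr.V_L == -75.0 and inh.V_L == -75.0

    def test_pyramidal_only_flag(self):
        cfg = TrialConfig(V_L=-75.0, rmp_pyramidal_only=True)
        pyr, inh = cfg.effective_neuron_params()
        assert pyr.V_L == -75.0 and inh.V_L == -70.0

    def test_digest_distinguishes_configs(self):
        assert TrialConfig().digest() != TrialConfig(w_plus=1.8).digest()
        assert TrialConfig().digest() == TrialConfig().digest()

    def test_size_compensation_scales_recurrent_conductances_only(self):
        cfg = TrialConfig()
        cp, ci = cfg.effective_conductances()
        scale = 2000 / 480
        assert cp.g_ext_AMPA == 2.1  # external drive untouched
        assert cp.g_rec_AMPA == pytest.approx(0.05 * scale)
        assert cp.g_NMDA == pytest.approx(0.165 * scale)
        assert ci.g_GABA == pytest.approx(1.0 * scale)


class TestRunTrial:
    def test_deterministic_given_seed(self, short_trial_cfg):
        r1 = run_trial(short_trial_cfg)
        r2 = run_trial(short_trial_cfg)
        assert np.array_equal(r1.spike_times, r2.spike_times)
        assert np.array_equal(r1.spike_ids, r2.spike_ids)
        assert r1.reaction_time == r2.reaction_time

    def test_different_seed_changes_raster(self, short_trial_cfg):
        r1 = run_trial(short_trial_cfg)
        r2 = run_trial(replace(short_trial_cfg, seed=short_trial_cfg.seed + 1))
        assert not np.array_equal(r1.spike_times, r2.spike_times)

    def test_raster_and_rt_invariants(self, short_trial_cfg):
        res = run_trial(short_trial_cfg)
        assert np.all((res.spike_times >= 0) & (res.spike_times <= short_trial_cfg.total_duration))
        assert np.all(np.diff(res.spike_times) >= 0)
        if res.reaction_time is not None:
            assert res.reaction_time >= 0
        # rate conservation across the four populations
        total = sum(tr.rates.sum() * tr.group_size * tr.window * 1e-3
                    for tr in res.traces.values())
        assert total == pytest.approx(res.n_spikes)

    def test_refractory_period_respected(self, short_trial_cfg):
        res = run_trial(short_trial_cfg)
        order = np.lexsort((res.spike_times, res.spike_ids))
        ids, times = res.spike_ids[order], res.spike_times[order]
        same = ids[1:] == ids[:-1]
        isi = (times[1:] - times[:-1])[same]
        tau_ref = np.where(ids[1:][same] < 384, 2.0, 1.0)
        assert np.all(isi >= tau_ref - 1e-9)


class TestSpontaneousState:
    def test_stationary_without_stimulus(self):
        """Without a stimulus at w+ = 1.9 the network stays in its low-rate
        spontaneous state: excitatory population rates below 10 spikes/s."""
        cfg = TrialConfig(total_duration=1500.0, w_plus=1.9, seed=21,
                          stimulus=StimulusProtocol(onset=100.0, duration=100.0,
                                                    rate_increment=0.0),
                          persistence_window=300.0)
        res = run_trial(cfg)
        for label in ("A", "B", "nonselective"):
            tr = res.traces[label]
            sel = (tr.centers >= 500.0) & (tr.centers <= 1500.0)
            assert tr.rates[sel].mean() < 10.0
        assert res.reaction_time is None


class TestSweep:
    def test_derive_seed_stable_and_disjoint(self):
        s1 = derive_seed(7, -70.0, 1.9, 0)
        assert s1 == derive_seed(7, -70.0, 1.9, 0)
        assert s1 != derive_seed(7, -70.0, 1.9, 1)
        assert s1 != derive_seed(7, -71.5, 1.9, 0)
        assert s1 != derive_seed(8, -70.0, 1.9, 0)
        assert 0 <= s1 < 2**31

    def test_degenerate_sweep_equals_trial(self, short_trial_cfg):
        sweep = run_sweep([(-70.0, 1.9)], 1, short_trial_cfg)
        cell = sweep.cells[0]
        cfg = replace(short_trial_cfg, V_L=-70.0, w_plus=1.9,
                      seed=derive_seed(short_trial_cfg.seed, -70.0, 1.9, 0))
        res = run_trial(cfg)
        assert cell.reaction_times == [res.reaction_time]
        assert cell.persistent == [res.persistent]

    def test_sweep_shape_and_flags(self, short_trial_cfg):
        sweep = run_sweep([(-70.0, 1.9), (-70.0, 1.0)], 2, short_trial_cfg)
        assert len(sweep.cells) == 2
        for cell in sweep.cells:
            assert len(cell.reaction_times) == 2
            assert cell.no_decision == (len(cell.deciding) == 0)
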