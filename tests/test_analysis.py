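"""Tests of rate estimation, reaction-time, persistence, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtanet import (PFC_REFERENCE, PPC_REFERENCE, compare_conditions,
                    detect_persistence, population_rate, reaction_time,
                    summarize_sweep)
from wtanet.analysis import CellResult, RateTrace, SweepResult


def make_trace(rates, window=20.0):
    rates = np.asarray(rates, dtype=float)
    centers = (np.arange(rates.size) + 0.5) * window
    return RateTrace(centers=centers, rates=rates, window=window, group_size=96)


class TestPopulationRate:
    def test_empty_raster_gives_zero(self):
        tr = population_rate(np.array([]), np.array([]), np.arange(96), 200.0)
        assert np.all(tr.rates == 0)

    def test_48_spikes_in_one_window_is_25_hz(self):
        times = np.full(48, 10.0)
        ids = np.arange(48)
        tr = population_rate(times, ids, np.arange(96), 20.0)
        assert tr.rates[0] == pytest.approx(25.0)

    def test_every_cell_twice_is_100_hz(self):
        times = np.full(192, 5.0)
        ids = np.repeat(np.arange(96), 2)
        tr = population_rate(times, ids, np.arange(96), 20.0)
        assert tr.rates[0] == pytest.approx(100.0)

    def test_spikes_from_other_groups_excluded(self):
        times = np.array([1.0, 2.0, 3.0])
        ids = np.array([0, 100, 200])
        tr = population_rate(times, ids, np.arange(96), 20.0)
        assert tr.rates[0] == pytest.approx(1 / (96 * 0.02))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            population_rate(np.array([1.0]), np.array([0]), np.array([]), 20.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=0, max_value=2**31 - 1))
    def test_rate_conservation(self, n_spikes, seed):
        # sum(rate * group_size * window) over windows recovers the spike count
        rng = np.random.default_rng(seed)
        times = rng.uniform(0, 400.0, n_spikes)
        ids = rng.integers(0, 96, n_spikes)
        tr = population_rate(times, ids, np.arange(96), 400.0)
        total = np.sum(tr.rates) * 96 * (tr.window * 1e-3)
        assert total == pytest.approx(n_spikes)


class TestReactionTime:
    def test_immediate_crossing_within_first_window(self):
        tr = make_trace([30.0] * 50)
        rt = reaction_time(tr, 25.0, onset=100.0)
        assert rt is not None and rt <= tr.window

    def test_subthreshold_trace_gives_none(self):
        assert reaction_time(make_trace([10.0] * 50), 25.0, 0.0) is None

    def test_step_trace_crossing_time(self):
        # 0 Hz before 700 ms, 26 Hz after; onset 500 -> RT 200 (+- one window)
        rates = [0.0 if c < 700 else 26.0 for c in (np.arange(50) + 0.5) * 20.0]
        rt = reaction_time(make_trace(rates), 25.0, onset=500.0)
        assert abs(rt - 200.0) <= 20.0

    def test_crossings_before_onset_ignored(self):
        rates = [30.0] * 10 + [0.0] * 40
        assert reaction_time(make_trace(rates), 25.0, onset=400.0) is None

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=5, max_size=50),
           st.floats(min_value=1, max_value=40))
    def test_nonincreasing_under_pointwise_increase(self, rates, thr):
        tr_lo = make_trace(rates)
        tr_hi = make_trace(np.asarray(rates) + 5.0)
        rt_lo = reaction_time(tr_lo, thr, 0.0)
        rt_hi = reaction_time(tr_hi, thr, 0.0)
        if rt_lo is not None:
            assert rt_hi is not None and rt_hi <= rt_lo


class TestPersistence:
    def test_decayed_rate_is_not_persistent(self):
        rates = [30.0] * 25 + [0.0] * 50
        assert not detect_persistence(make_trace(rates), stim_offset=500.0, horizon=300.0)

    def test_sustained_rate_is_persistent(self):
        assert detect_persistence(make_trace([35.0] * 75), stim_offset=500.0, horizon=300.0)

    def test_monotone_in_criterion(self):
        tr = make_trace([12.0] * 75)
        flags = [detect_persistence(tr, 500.0, 300.0, c) for c in (5.0, 10.0, 12.0, 20.0)]
        # once False at some criterion, False for all larger criteria
        assert flags == sorted(flags, reverse=True)

    def test_horizon_before_offset_rejected(self):
        with pytest.raises(ValueError):
            detect_persistence(make_trace([1.0] * 10), stim_offset=150.0, horizon=200.0)


class TestCompareConditions:
    def test_identical_samples(self):
        diff, (lo, hi) = compare_conditions([200, 220, 240], [200, 220, 240], seed=1)
        assert diff == 0.0 and lo <= 0.0 <= hi

    def test_mean_difference(self):
        diff, _ = compare_conditions([300, 320], [200, 220], seed=1)
        assert diff == pytest.approx(100.0)

    def test_separated_samples_exclude_zero(self):
        rng = np.random.default_rng(0)
        a = 400 + rng.normal(0, 10, 20)
        b = 200 + rng.normal(0, 10, 20)
        diff, (lo, hi) = compare_conditions(a, b, seed=2)
        assert lo > 0 and diff == pytest.approx(200, abs=20)

    def test_insufficient_trials_error_names_condition(self):
        with pytest.raises(ValueError, match="condition b"):
            compare_conditions([100, 200], [300, None])


class TestSummarizeSweep:
    def _sweep(self):
        cells = [
            CellResult(V_L=-80.0, w_plus=1.8, reaction_times=[None, None, None]),
            CellResult(V_L=-70.0, w_plus=1.8, reaction_times=[100.0, 200.0, None]),
        ]
        return SweepResult(V_L_values=[-80.0, -70.0], w_plus_values=[1.8], cells=cells)

    def test_exclusion_rule_and_flags(self):
        table = summarize_sweep(self._sweep())
        assert len(table) == 2
        dead = table[table.V_L == -80.0].iloc[0]
        live = table[table.V_L == -70.0].iloc[0]
        assert bool(dead.no_decision) and np.isnan(dead.mean_rt)
        assert not bool(live.no_decision)
        assert live.n_deciding == 2 and live.mean_rt == pytest.approx(150.0)

    def test_row_count_is_grid_size(self):
        table = summarize_sweep(self._sweep())
        assert len(table) == len(self._sweep().cells)


class TestEphysReference:
    def test_resting_potentials_stored_as_negative(self):
        assert PPC_REFERENCE.rmp_mean == pytest.approx(-84.29)
        assert PFC_REFERENCE.rmp_mean == pytest.approx(-76.12)
        assert PFC_REFERENCE.rmp_mean > PPC_REFERENCE.rmp_mean

    def test_sems_and_counts_positive(self):
        for ref in (PPC_REFERENCE, PFC_REFERENCE):
            assert ref.rmp_sem > 0 and ref.n_cells > 0
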