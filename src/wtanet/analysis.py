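"""Population-rate estimation and decision statistics.

Population firing rates are computed in non-overlapping 20-ms windows
anchored at t = 0: the spike count of a group in a window divided by the
group size and the window length.  The reaction time of a trial is the
time from stimulus onset until the winner population's windowed rate first
reaches 25 spikes/s; trials in which no group crosses the threshold carry
no reaction time and are excluded from averages.  Persistent activity is
scored on the final stretch of the trial, after stimulus offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RateTrace", "population_rate", "reaction_time", "detect_persistence",
    "compare_conditions", "CellResult", "SweepResult", "summarize_sweep",
    "EphysReference", "PPC_REFERENCE", "PFC_REFERENCE",
    "RT_THRESHOLD", "RATE_WINDOW", "PERSISTENCE_RATE", "PERSISTENCE_WINDOW",
]

#: Rate (spikes/s) a population must reach for a decision / reaction time.
RT_THRESHOLD = 25.0
#: Length (ms) of the non-overlapping rate windows.
RATE_WINDOW = 20.0
#: Mean winner rate (spikes/s) over the final PERSISTENCE_WINDOW ms that
#: counts as persistent delay activity.
PERSISTENCE_RATE = 10.0
PERSISTENCE_WINDOW = 500.0


@dataclass
class RateTrace:
    """Windowed population firing rate.

    ``centers`` are window midpoints in ms; ``rates`` in spikes/s;
    ``window`` the window length in ms; ``group_size`` the population size
    used for normalization.
    """

    centers: np.ndarray
    rates: np.ndarray
    window: float
    group_size: int

    def rate_at_or_after(self, t: float) -> np.ndarray:
        return self.rates[self.centers >= t]


def population_rate(spike_times: np.ndarray, spike_ids: np.ndarray,
                    group: np.ndarray, total_duration: float,
                    window: float = RATE_WINDOW) -> RateTrace:
    """Windowed firing rate of one population.

    rate = (# spikes from `group` members in the window) / (|group| * window),
    with the window length converted to seconds so rates are in spikes/s.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("group must be nonempty")
    n_windows = int(np.ceil(total_duration / window))
    edges = np.arange(n_windows + 1) * window
    mask = np.isin(spike_ids, group)
    counts, _ = np.histogram(spike_times[mask], bins=edges)
    rates = counts / (group.size * window * 1e-3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RateTrace(centers=centers, rates=rates, window=window, group_size=group.size)


def reaction_time(trace: RateTrace, threshold: float = RT_THRESHOLD,
                  onset: float = 0.0) -> float | None:
    """Time from onset to the first window (centered at or after onset) with
    rate >= threshold, or None if the trace never crosses."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sel = trace.centers >= onset
    idx = np.nonzero(sel & (trace.rates >= threshold))[0]
    if idx.size == 0:
        return None
    return float(trace.centers[idx[0]] - onset)


def detect_persistence(trace: RateTrace, stim_offset: float,
                       horizon: float = PERSISTENCE_WINDOW,
                       criterion_rate: float = PERSISTENCE_RATE) -> bool:
    """True iff the population's mean rate over the final ``horizon`` ms of
    the trace (which must lie after stimulus offset) reaches ``criterion_rate``."""
    t_end = trace.centers[-1] + trace.window / 2
    t_start = t_end - horizon
    if t_start < stim_offset:
        raise ValueError(
            f"persistence horizon {horizon} ms reaches back before stimulus offset {stim_offset} ms")
    sel = trace.centers >= t_start
    if not np.any(sel):
        raise ValueError("horizon exceeds trace extent")
    return bool(np.mean(trace.rates[sel]) >= criterion_rate)


def compare_conditions(rts_a, rts_b, n_boot: int = 10_000,
                       seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Difference of mean reaction times (a - b) with a percentile bootstrap 95% CI.

    Both samples must contain at least two deciding trials (None entries are
    rejected here; filter them upstream).
    """
    a = np.asarray([r for r in rts_a if r is not None], dtype=float)
    b = np.asarray([r for r in rts_b if r is not None], dtype=float)
    for name, arr in (("a", a), ("b", b)):
        if arr.size < 2:
            raise ValueError(f"condition {name} has {arr.size} deciding trials; need at least 2")
    diff = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    boots = (a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
             - b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, (float(lo), float(hi))


@dataclass
class CellResult:
    """Trial batch at one (V_L, w_plus) grid cell."""

    V_L: float
    w_plus: float
    reaction_times: list  # per trial, ms or None
    persistent: list = field(default_factory=list)  # per trial bool
    seeds: list = field(default_factory=list)

    @property
    def deciding(self) -> list[float]:
        return [r for r in self.reaction_times if r is not None]

    @property
    def mean_rt(self) -> float | None:
        d = self.deciding
        return float(np.mean(d)) if d else None

    @property
    def no_decision(self) -> bool:
        return len(self.deciding) == 0


@dataclass
class SweepResult:
    """Grid of trial batches over resting potential and recurrent weight."""

    V_L_values: list
    w_plus_values: list
    cells: list  # of CellResult, row-major over (V_L, w_plus)

    def cell(self, V_L: float, w_plus: float) -> CellResult:
        for c in self.cells:
            if np.isclose(c.V_L, V_L) and np.isclose(c.w_plus, w_plus):
                return c
        raise KeyError(f"no cell at V_L={V_L}, w_plus={w_plus}")


def summarize_sweep(result: SweepResult) -> pd.DataFrame:
    """Long-format table: one row per grid cell.

    Columns: V_L, w_plus, n_trials, n_deciding, mean_rt (NaN when no trial
    decided), no_decision (the all-black condition of the heatmap).
    """
    rows = []
    for c in result.cells:
        rows.append({
            "V_L": c.V_L,
            "w_plus": c.w_plus,
            "n_trials": len(c.reaction_times),
            "n_deciding": len(c.deciding),
            "mean_rt": c.mean_rt if c.mean_rt is not None else np.nan,
            "no_decision": c.no_decision,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EphysReference:
    """Whole-cell recording summary statistics, stored for reporting.

    RMPs are stored as negative potentials (the magnitudes are sometimes
    quoted without sign; resting potentials are below zero).
    """

    region: str
    rmp_mean: float          # mV
    rmp_sem: float
    rheobase_mean: float     # pA
    rheobase_sem: float
    input_resistance_mean: float  # MOhm
    input_resistance_sem: float
    capacitance_mean: float  # pF
    capacitance_sem: float
    threshold_change_mean: float  # mV to trigger an action potential
    threshold_change_sem: float
    n_cells: int


PPC_REFERENCE = EphysReference(
    region="PPC", rmp_mean=-84.29, rmp_sem=1.52,
    rheobase_mean=213.15, rheobase_sem=13.70,
    input_resistance_mean=72.53, input_resistance_sem=3.96,
    capacitance_mean=39.61, capacitance_sem=3.23,
    threshold_change_mean=47.85, threshold_change_sem=1.75,
    n_cells=19,
)

PFC_REFERENCE = EphysReference(
    region="PFC", rmp_mean=-76.12, rmp_sem=0.89,
    rheobase_mean=115.625, rheobase_sem=16.90,
    input_resistance_mean=97.92, input_resistance_sem=6.47,
    capacitance_mean=40.05, capacitance_sem=2.96,
    threshold_change_mean=36.87, threshold_change_sem=1.83,
    n_cells=13,
)
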