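"""Delimited-text readers and writers for rasters, rate traces, and sweep tables."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["write_raster", "read_raster", "write_rate_traces", "write_sweep_table"]

RASTER_HEADER = "time_ms\tneuron_id"


def write_raster(path, spike_times: np.ndarray, spike_ids: np.ndarray) -> None:
    """Write a spike raster as tab-separated (time_ms, neuron_id) records.

    The raster must be sorted by time.
    """
    t = np.asarray(spike_times, dtype=float)
    ids = np.asarray(spike_ids)
    if t.shape != ids.shape:
        raise ValueError("spike_times and spike_ids must have the same length")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("raster must be sorted by time")
    with open(path, "w") as fh:
        fh.write(RASTER_HEADER + "\n")
        for ti, ni in zip(t, ids):
            fh.write(f"{ti:.6g}\t{int(ni)}\n")


def read_raster(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a raster written by :func:`write_raster`; round-trip identity."""
    times, ids = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != RASTER_HEADER:
            raise ValueError(f"{path}: line 1: expected header {RASTER_HEADER!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            try:
                times.append(float(parts[0]))
                ids.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return np.asarray(times, dtype=float), np.asarray(ids, dtype=np.int64)


def write_rate_traces(path, traces: dict) -> None:
    """Write population rate traces as CSV (time_ms, r_A, r_B, r_nonsel, r_inh)."""
    cols = {"time_ms": traces["A"].centers}
    for label, col in (("A", "r_A"), ("B", "r_B"),
                       ("nonselective", "r_nonsel"), ("inhibitory", "r_inh")):
        if label in traces:
            cols[col] = traces[label].rates
    pd.DataFrame(cols).to_csv(path, index=False)


def write_sweep_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
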