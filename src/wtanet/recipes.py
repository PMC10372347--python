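"""Canned experiment recipes: the four headline simulation figures.

Each recipe runs a self-contained experiment into an output directory:
spike rasters and/or rate-trace CSVs, a summary JSON, a run manifest, and a
plain-text log.  ``scale="smoke"`` runs the same protocol at reduced trial
counts for quick checks; ``scale="full"`` matches the figure-sized runs.

  ramping    population rates at three recurrent strengths (w+ sweep)
  rmp_rt     reaction-time distributions at low vs high resting potential
  heatmap    mean reaction time over the (resting potential, w+) grid
  nmda_rmp   single-cell resting potential vs NMDA kinetics and strength
"""

from __future__ import annotations

import json
import os
from dataclasses import replace

import numpy as np

from . import analysis, io
from .config import RunManifest
from .protocol import TrialConfig, derive_seed, run_sweep, run_trial
from .single_cell import SingleCellConfig, run_single_cell

__all__ = ["reproduce", "RECIPES", "DEFAULT_VL_GRID", "DEFAULT_WPLUS_GRID"]

#: Resting-potential grid of the reaction-time heatmap (mV).
DEFAULT_VL_GRID = [-80.0, -78.5, -77.5, -76.0, -74.5, -73.0, -71.5, -70.0]
#: Recurrent-strength grid (range where the network holds persistent activity
#: without exceeding ~100 spikes/s).
DEFAULT_WPLUS_GRID = [1.7, 1.8, 1.9, 2.0, 2.1, 2.2]


def _log(outdir, lines):
    with open(os.path.join(outdir, "run.log"), "a") as fh:
        for line in lines if isinstance(lines, list) else [lines]:
            fh.write(line + "\n")


def _write_summary(outdir, manifest, payload):
    path = os.path.join(outdir, "summary.json")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    manifest.outputs.append("summary.json")
    manifest.finish()
    manifest.save(os.path.join(outdir, "manifest.json"))


def fig3(base_cfg: TrialConfig, scale: str, seed: int, outdir: str) -> dict:
    """Population ramping at w+ in {1.7, 2.0, 2.2} (stimulus to group A)."""
    n_trials = 5 if scale == "full" else 1
    cfg0 = replace(base_cfg, seed=seed)
    manifest = RunManifest.begin(cfg0, seed)
    summary = {"w_plus": {}, "n_trials": n_trials}
    for w in (1.7, 2.0, 2.2):
        entries = []
        for k in range(n_trials):
            s = derive_seed(seed, base_cfg.V_L, w, k)
            res = run_trial(replace(base_cfg, w_plus=w, seed=s))
            manifest.trial_seeds.append(s)
            name = f"rates_w{w:.1f}_trial{k}.csv"
            io.write_rate_traces(os.path.join(outdir, name), res.traces)
            manifest.outputs.append(name)
            if k == 0:
                rname = f"raster_w{w:.1f}_trial0.tsv"
                io.write_raster(os.path.join(outdir, rname), res.spike_times, res.spike_ids)
                manifest.outputs.append(rname)
            entries.append({"seed": s, "reaction_time": res.reaction_time,
                            "winner": res.winner, "persistent": res.persistent})
            _log(outdir, f"w+={w} trial {k}: RT={res.reaction_time} winner={res.winner}")
        summary["w_plus"][str(w)] = entries
    _write_summary(outdir, manifest, summary)
    return summary


def fig4(base_cfg: TrialConfig, scale: str, seed: int, outdir: str) -> dict:
    """Reaction-time distributions at resting potentials -80 vs -70 mV."""
    n_trials = 100 if scale == "full" else 10
    cfg0 = replace(base_cfg, seed=seed)
    manifest = RunManifest.begin(cfg0, seed)
    summary = {"n_trials": n_trials, "conditions": {}}
    for v_l in (-80.0, -70.0):
        rts, mean_rates = [], None
        for k in range(n_trials):
            s = derive_seed(seed, v_l, base_cfg.w_plus, k)
            res = run_trial(replace(base_cfg, V_L=v_l, seed=s))
            manifest.trial_seeds.append(s)
            rts.append(res.reaction_time)
            rate = res.traces["A"].rates
            mean_rates = rate if mean_rates is None else mean_rates + rate
            _log(outdir, f"V_L={v_l} trial {k}: RT={res.reaction_time} winner={res.winner}")
        mean_rates = mean_rates / n_trials
        name = f"mean_rate_VL{v_l:+.0f}.csv"
        np.savetxt(os.path.join(outdir, name),
                   np.column_stack([res.traces["A"].centers, mean_rates]),
                   delimiter=",", header="time_ms,r_A_mean", comments="")
        manifest.outputs.append(name)
        deciding = [r for r in rts if r is not None]
        summary["conditions"][str(v_l)] = {
            "reaction_times": rts,
            "n_deciding": len(deciding),
            "median_rt": float(np.median(deciding)) if deciding else None,
        }
    _write_summary(outdir, manifest, summary)
    return summary


def fig5(base_cfg: TrialConfig, scale: str, seed: int, outdir: str) -> dict:
    """Mean reaction time over the (V_L, w+) grid; no-decision cells flagged."""
    n_trials = 10 if scale == "full" else 3
    grid = [(v, w) for v in DEFAULT_VL_GRID for w in DEFAULT_WPLUS_GRID]
    cfg0 = replace(base_cfg, seed=seed)
    manifest = RunManifest.begin(cfg0, seed)
    sweep = run_sweep(grid, n_trials, cfg0)
    table = analysis.summarize_sweep(sweep)
    io.write_sweep_table(os.path.join(outdir, "sweep_table.csv"), table)
    manifest.outputs.append("sweep_table.csv")
    manifest.trial_seeds = [s for c in sweep.cells for s in c.seeds]
    _log(outdir, [f"cell V_L={c.V_L} w+={c.w_plus}: mean_rt={c.mean_rt} "
                  f"no_decision={c.no_decision}" for c in sweep.cells])
    summary = {"n_trials": n_trials, "table": table.to_dict(orient="records")}
    _write_summary(outdir, manifest, summary)
    return summary


def fig6(base_cfg: TrialConfig, scale: str, seed: int, outdir: str) -> dict:
    """Single-cell RMP vs NMDA decay time constant and input strength."""
    n_trials = 100 if scale == "full" else 10
    manifest = RunManifest.begin(replace(base_cfg, seed=seed), seed)
    summary = {"n_trials": n_trials, "conditions": {}}
    for tau in (100.0, 2.0):
        for strength in (1.0, 2.0):
            rmps = []
            for k in range(n_trials):
                s = derive_seed(seed, tau, strength, k)
                res = run_single_cell(SingleCellConfig(
                    tau_NMDA_decay=tau, strength_scale=strength, seed=s))
                manifest.trial_seeds.append(s)
                rmps.append(res.rmp)
                if k == 0:
                    name = f"vtrace_tau{tau:.0f}_scale{strength:.0f}.csv"
                    step = 50  # 1-ms resolution is plenty for inspection
                    np.savetxt(os.path.join(outdir, name),
                               np.column_stack([res.time[::step], res.V[::step]]),
                               delimiter=",", header="time_ms,V_mV", comments="")
                    manifest.outputs.append(name)
            key = f"tau{tau:.0f}_scale{strength:.0f}"
            summary["conditions"][key] = {
                "rmp_mean": float(np.mean(rmps)),
                "rmp_sem": float(np.std(rmps, ddof=1) / np.sqrt(len(rmps))) if len(rmps) > 1 else None,
                "rmps": rmps,
            }
            _log(outdir, f"tau={tau} scale={strength}: RMP {np.mean(rmps):.2f} mV")
    _write_summary(outdir, manifest, summary)
    return summary


RECIPES = {"fig3": fig3, "fig4": fig4, "fig5": fig5, "fig6": fig6}


def reproduce(figure: str, scale: str = "smoke", seed: int = 0,
              base_cfg: TrialConfig | None = None, outdir: str = "out") -> dict:
    """Run one reproduction recipe; returns its summary dict."""
    if figure not in RECIPES:
        raise ValueError(f"unknown figure {figure!r}; choose from {sorted(RECIPES)}")
    if scale not in ("smoke", "full"):
        raise ValueError("scale must be 'smoke' or 'full'")
    base_cfg = base_cfg if base_cfg is not None else TrialConfig()
    io.ensure_dir(outdir)
    return RECIPES[figure](base_cfg, scale, seed, outdir)
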