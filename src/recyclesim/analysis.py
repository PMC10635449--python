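"""Landscape-level analyses of sweep outputs.

Builds the tidy tables behind the headline patterns: per-run
coefficients of variation of every square-level output, per-run
exposure tests (are recycled artifacts the longer-exposed ones?),
per-square Spearman correlations of recycling incidence with behavioral
events across runs, recycling-incidence-vs-density and vs-cortex-ratio
regression inputs, and queen-contiguity local-G hotspot masks with
overlap counts against the recycling-incidence hotspots.  Any model
fitting on these tables (logistic, zero-inflated, ...) is left to
external tools; this module only computes and emits the inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from recyclesim.simulation import OutputTables
from recyclesim.stats import (
    HotspotMask,
    cov,
    exposure_test,
    hotspot_mask,
    hotspot_overlap,
    local_g,
    skewness,
    spearman,
)
from recyclesim.sweep import (
    SQUARE_OUTPUTS,
    final_snapshot,
    summarize_run,
    summarize_runs,
)

__all__ = [
    "HotspotMask", "cov", "skewness", "exposure_test", "spearman",
    "local_g", "hotspot_mask", "hotspot_overlap",
    "snapshot_field", "analysis_report", "sweep_statistics",
    "headline_statistics", "write_report",
    "BEHAVIOR_OUTPUTS", "HOTSPOT_OUTPUTS",
]

#: Behavioral event counters correlated with recycling incidence.
BEHAVIOR_OUTPUTS = ["discard_events", "scavenge_events", "encounters",
                    "retouch_events"]

#: Square outputs whose hotspots are compared against recycling incidence.
HOTSPOT_OUTPUTS = ["object_count", "flake_count", "nodule_count",
                   "discard_events", "scavenge_events", "encounters",
                   "retouch_events"]

_META_COLS = ["combination_id", "replicate", "seed"]


def snapshot_field(snapshot: pd.DataFrame, variable: str) -> np.ndarray:
    """Pivot one snapshot variable into a (height, width) array."""
    height = int(snapshot["row"].max()) + 1
    width = int(snapshot["col"].max()) + 1
    field = np.full((height, width), np.nan)
    rows = snapshot["row"].to_numpy(int)
    cols = snapshot["col"].to_numpy(int)
    field[rows, cols] = snapshot[variable].to_numpy(float)
    return field


def _meta_cols(meta: dict) -> dict:
    return {k: meta.get(k) for k in _META_COLS if k in meta}


def _cov_table(runs) -> pd.DataFrame:
    summary = summarize_runs(runs)
    keep = [c for c in _META_COLS if c in summary.columns]
    keep += [f"cov_{v}" for v in SQUARE_OUTPUTS] + ["cov_cortex_ratio"]
    return summary[keep].copy()


def _exposure_table(runs) -> pd.DataFrame:
    rows = []
    for meta, tables in runs:
        art = tables.artifacts_final
        years = art["year_first_discard"].to_numpy(float)
        recycled = art["recycled"].astype(bool).to_numpy()
        rec_years = years[recycled]
        non_years = years[~recycled]
        stat, p = exposure_test(rec_years, non_years)
        rows.append({
            **_meta_cols(meta),
            "n_recycled": int(recycled.sum()),
            "n_nonrecycled": int((~recycled).sum()),
            "skew_first_discard": skewness(years),
            "statistic": stat,
            "p_value": p,
            "recycled_older": bool(np.isfinite(p) and p < 0.05),
        })
    return pd.DataFrame(rows)


def _spearman_table(runs) -> pd.DataFrame:
    """RI-vs-behavior rank correlations per grid square across runs."""
    frames = []
    for i, (meta, tables) in enumerate(runs):
        snap = final_snapshot(tables)[
            ["row", "col", "recycling_incidence"] + BEHAVIOR_OUTPUTS].copy()
        snap["run"] = i
        frames.append(snap)
    stacked = pd.concat(frames, ignore_index=True)
    rows = []
    for (r, c), group in stacked.groupby(["row", "col"]):
        for var in BEHAVIOR_OUTPUTS:
            rows.append({
                "row": r, "col": c, "variable": var,
                "rho": spearman(group["recycling_incidence"], group[var]),
                "n_runs": len(group),
            })
    return pd.DataFrame(rows)


def _density_table(runs) -> pd.DataFrame:
    """Per-square RI, log object count and cortex ratio (regression inputs)."""
    rows = []
    for meta, tables in runs:
        snap = final_snapshot(tables)
        counts = (snap["flake_count"] + snap["nodule_count"]).to_numpy(float)
        log_counts = np.full_like(counts, np.nan)
        pos = counts > 0
        log_counts[pos] = np.log(counts[pos])
        base = _meta_cols(meta)
        for j in range(len(snap)):
            rows.append({
                **base,
                "row": int(snap["row"].iloc[j]),
                "col": int(snap["col"].iloc[j]),
                "recycling_incidence": float(snap["recycling_incidence"].iloc[j]),
                "object_count": counts[j],
                "log_object_count": log_counts[j],
                "cortex_ratio": float(snap["cortex_ratio"].iloc[j]),
            })
    return pd.DataFrame(rows)


def _hotspot_table(runs) -> pd.DataFrame:
    """Local-G hotspot counts per output and overlap with RI hotspots."""
    rows = []
    for meta, tables in runs:
        snap = final_snapshot(tables).copy()
        snap["object_count"] = snap["flake_count"] + snap["nodule_count"]
        ri_mask = hotspot_mask(local_g(snapshot_field(snap, "recycling_incidence")))
        base = _meta_cols(meta)
        for var in HOTSPOT_OUTPUTS:
            var_mask = hotspot_mask(local_g(snapshot_field(snap, var)))
            rows.append({
                **base,
                "variable": var,
                "n_hotspots": var_mask.count,
                "n_hotspots_ri": ri_mask.count,
                "overlap": hotspot_overlap(var_mask, ri_mask),
                "n_cells": int(var_mask.mask.size),
            })
    return pd.DataFrame(rows)


def analysis_report(runs) -> dict[str, pd.DataFrame]:
    """All analysis tables for a completed sweep.

    ``runs`` is a list of ``(meta, OutputTables)``; an empty sweep is an
    error.  Returns a dict of DataFrames keyed by analysis name:
    ``cov``, ``exposure``, ``spearman_by_square``, ``density_inputs``,
    ``hotspot_overlap``.  Re-running on identical inputs is
    byte-identical.
    """
    runs = [(m, t) for m, t in runs if t is not None]
    if not runs:
        raise ValueError("analysis_report requires at least one completed run")
    return {
        "cov": _cov_table(runs),
        "exposure": _exposure_table(runs),
        "spearman_by_square": _spearman_table(runs),
        "density_inputs": _density_table(runs),
        "hotspot_overlap": _hotspot_table(runs),
    }


def sweep_statistics(plan) -> dict[str, pd.DataFrame]:
    """Run a sweep and collect per-run statistics, streaming.

    Executes every run of the plan but keeps only the derived rows
    (landscape summary with COVs, exposure test, hotspot counts), so
    arbitrarily large sweeps fit in memory.  Equivalent to
    ``run_sweep`` followed by :func:`analysis_report` restricted to the
    per-run tables.
    """
    from recyclesim.sweep import _execute_spec

    summary_rows = []
    exposure_frames = []
    hotspot_frames = []
    for spec in plan.run_specs():
        meta, tables = _execute_spec(spec)
        if tables is None:
            summary_rows.append(meta)
            continue
        run = [(meta, tables)]
        summary_rows.append({**meta, **summarize_run(tables)})
        exposure_frames.append(_exposure_table(run))
        hotspot_frames.append(_hotspot_table(run))
    return {
        "summary": pd.DataFrame(summary_rows),
        "exposure": pd.concat(exposure_frames, ignore_index=True),
        "hotspot": pd.concat(hotspot_frames, ignore_index=True),
    }


def headline_statistics(stats: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Landscape-level headline numbers from streamed sweep statistics.

    Aggregates the per-run statistics of :func:`sweep_statistics` into
    the summary pattern set: mean COV of every square-level output over
    all runs, mean hotspot fractions (share of grid squares whose local
    G exceeds mean + 2 SD), the mean overlap between recycling-incidence
    and scavenging hotspots, the share of non-strict parameter sets in
    which recycled artifacts entered the discard record significantly
    earlier, and the mobility/occupation trends of the recycling-
    incidence COV.  Percentages are on a 0-100 scale.
    """
    summary = stats["summary"]
    if "status" in summary.columns:
        summary = summary[summary["status"] == "ok"]
    out: dict[str, float] = {}
    for var in SQUARE_OUTPUTS + ["cortex_ratio"]:
        out[f"mean_cov_{var}"] = float(np.nanmean(summary[f"cov_{var}"]))

    hs = stats["hotspot"]
    frac_by_var = hs.groupby("variable").apply(
        lambda g: (g["n_hotspots"] / g["n_cells"]).mean(), include_groups=False)
    ri_frac = float((hs["n_hotspots_ri"] / hs["n_cells"]).mean())
    all_fracs = list(frac_by_var) + [ri_frac]
    out["hotspot_fraction_mean_pct"] = 100.0 * float(np.mean(all_fracs))
    out["hotspot_fraction_scavenging_pct"] = \
        100.0 * float(frac_by_var["scavenge_events"])
    scav = hs[hs["variable"] == "scavenge_events"]
    out["ri_scavenging_hotspot_overlap_pct"] = \
        100.0 * float((scav["overlap"] / scav["n_cells"]).mean())

    merged = stats["exposure"].merge(
        summary[["combination_id", "replicate", "strict_selection"]],
        on=["combination_id", "replicate"])
    nonstrict = merged[~merged["strict_selection"].astype(bool)]
    per_set = nonstrict.groupby("combination_id")["recycled_older"].mean()
    out["pct_nonstrict_sets_recycled_older"] = \
        100.0 * float((per_set > 0.5).mean())

    for mu, group in summary.groupby("mu"):
        out[f"mean_cov_recycling_incidence_mu{int(mu)}"] = \
            float(np.nanmean(group["cov_recycling_incidence"]))
    for n, group in summary.groupby("n_agents"):
        out[f"mean_cov_recycling_incidence_agents{int(n)}"] = \
            float(np.nanmean(group["cov_recycling_incidence"]))
    return out


def write_report(report: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write each analysis table as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
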