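"""Factorial parameter sweeps with replication and per-run summaries.

Every parameter combination receives ``replicates`` distinct seeds
derived deterministically from the plan's base seed and the combination
index, so a published sweep is replayable run by run and the results are
independent of execution order.
"""

from __future__ import annotations

import itertools
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from recyclesim.stats import cov
from recyclesim.config import SimulationConfig
from recyclesim.simulation import OutputTables, run_model

#: Square-level output variables summarised per run.
SQUARE_OUTPUTS = ["recycling_incidence", "flake_count", "nodule_count",
                  "discard_events", "scavenge_events", "retouch_events",
                  "encounters"]

_SEED_STRIDE = 10007  # combination stride in the seed schedule


def default_sweep_grid() -> dict[str, list]:
    """The default factorial grid over the experiment parameters."""
    return {
        "scavenge_prob": [0.25, 0.5, 0.75, 1.0],
        "blank_prob": [0.25, 0.5, 0.75],
        "mu": [1.0, 2.0, 3.0],
        "n_agents": [100, 200],
        "overlap": [1, 2],
        "flake_preference": [True, False],
        "size_preference": [True, False],
        "strict_selection": [True, False],
        "min_select_size": [2],
    }


def _canonicalize(params: dict) -> dict:
    """Collapse redundant selection combinations.

    A size preference only applies to flakes, so under a nodule
    preference it is a no-op; likewise ``min_select_size`` is inert
    without a size preference.  Collapsing these avoids running the
    same model twice under different labels.
    """
    params = dict(params)
    if not params.get("flake_preference", True):
        params["size_preference"] = False
    if not params.get("size_preference", False):
        params["min_select_size"] = 1
    return params


def expand_grid(grid: dict[str, list]) -> list[dict]:
    """Cartesian product of the grid, canonicalized and de-duplicated."""
    keys = list(grid)
    combos = []
    seen = set()
    for values in itertools.product(*(grid[k] for k in keys)):
        params = _canonicalize(dict(zip(keys, values)))
        key = tuple(sorted(params.items()))
        if key not in seen:
            seen.add(key)
            combos.append(params)
    return combos


def replicate_seed(base_seed: int, combination: int, replicate: int) -> int:
    """Deterministic seed schedule: ``base + combination*10007 + replicate``."""
    return base_seed + combination * _SEED_STRIDE + replicate


@dataclass
class SweepPlan:
    """A factorial sweep: parameter grid, replication and seed policy."""

    grid: dict[str, list] = field(default_factory=default_sweep_grid)
    replicates: int = 50
    base_seed: int = 0
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def combinations(self) -> list[dict]:
        return expand_grid(self.grid)

    def run_specs(self):
        """Yield ``(combination_id, replicate, seed, config)`` for every run."""
        for cid, params in enumerate(self.combinations()):
            for rep in range(self.replicates):
                seed = replicate_seed(self.base_seed, cid, rep)
                cfg = self.base_config.replace(seed=seed, **params)
                yield cid, rep, seed, cfg


def _execute_spec(spec):
    cid, rep, seed, cfg = spec
    meta = {"combination_id": cid, "replicate": rep, "seed": seed,
            **{k: v for k, v in cfg.to_dict().items() if k != "seed"}}
    try:
        tables = run_model(cfg)
        meta["status"] = "ok"
        return meta, tables
    except Exception as exc:  # partial failure: flag and continue
        meta["status"] = f"failed: {exc}"
        return meta, None


def run_sweep(plan: SweepPlan, out_dir: str | Path | None = None,
              jobs: int = 1, keep_tables: bool | None = None):
    """Execute every (combination, replicate) run of the plan.

    Parameters
    ----------
    plan
        The sweep plan.
    out_dir
        If given, each run's tables are written under
        ``out_dir/run_<combination>_<replicate>/`` and the index as
        ``out_dir/sweep_index.csv``.
    jobs
        Process-level parallelism; results are identical to serial
        execution because every run is independently seeded.
    keep_tables
        Whether to return the in-memory tables alongside the index
        (default: only when not writing to disk).

    Returns
    -------
    (index, runs)
        ``index`` is a DataFrame with one row per run; ``runs`` is a
        list of ``(meta, OutputTables)`` or ``None``.
    """
    if keep_tables is None:
        keep_tables = out_dir is None
    specs = list(plan.run_specs())
    if jobs > 1:
        with ProcessPoolExecutor(max_workers=jobs) as pool:
            results = list(pool.map(_execute_spec, specs, chunksize=4))
    else:
        results = [_execute_spec(s) for s in specs]

    index_rows = []
    kept = [] if keep_tables else None
    for meta, tables in results:
        row = dict(meta)
        if out_dir is not None and tables is not None:
            run_dir = Path(out_dir) / f"run_{meta['combination_id']}_{meta['replicate']}"
            tables.write(run_dir)
            row["run_dir"] = run_dir.name
        index_rows.append(row)
        if keep_tables:
            kept.append((meta, tables))
    index = pd.DataFrame(index_rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        index.to_csv(Path(out_dir) / "sweep_index.csv", index=False)
    return index, kept


def load_sweep(out_dir: str | Path):
    """Re-load a written sweep as ``(index, [(meta, OutputTables), ...])``.

    Raises ``FileNotFoundError`` listing the run ids whose outputs are
    missing.
    """
    out_dir = Path(out_dir)
    index = pd.read_csv(out_dir / "sweep_index.csv")
    runs = []
    missing = []
    for _, row in index.iterrows():
        meta = row.to_dict()
        if meta.get("status") != "ok":
            continue
        run_dir = out_dir / meta["run_dir"]
        try:
            tables = OutputTables(
                artifacts_mid=pd.read_csv(run_dir / "artifacts_mid.csv"),
                artifacts_final=pd.read_csv(run_dir / "artifacts_final.csv"),
                squares=pd.read_csv(run_dir / "squares.csv"),
                model=pd.read_csv(run_dir / "model.csv"),
            )
        except FileNotFoundError:
            missing.append(f"{meta['combination_id']}_{meta['replicate']}")
            continue
        runs.append((meta, tables))
    if missing:
        raise FileNotFoundError(f"missing run outputs for: {missing}")
    return index, runs


def final_snapshot(tables: OutputTables) -> pd.DataFrame:
    """The last recorded grid-square snapshot of a run."""
    squares = tables.squares
    last = squares["snapshot_year"].max()
    return squares[squares["snapshot_year"] == last]


def summarize_run(tables: OutputTables) -> dict:
    """Mean and COV of each square-level output at the final snapshot,
    plus the overall landscape cortex ratio and recycling incidence."""
    snap = final_snapshot(tables)
    out: dict = {}
    for var in SQUARE_OUTPUTS + ["cortex_ratio"]:
        values = snap[var].to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        out[f"mean_{var}"] = float(finite.mean()) if finite.size else float("nan")
        out[f"cov_{var}"] = cov(values)
    last_row = tables.model.iloc[-1]
    out["overall_recycling_incidence"] = float(last_row["recycling_incidence"])
    out["overall_cortex_ratio"] = float(last_row["cortex_ratio"])
    out["n_model_years"] = int(last_row["model_year"])
    return out


def summarize_runs(runs) -> pd.DataFrame:
    """Per-run landscape summaries: one row per completed run.

    ``runs`` is an iterable of ``(meta, OutputTables)`` as produced by
    :func:`run_sweep` or :func:`load_sweep`.
    """
    rows = []
    for meta, tables in runs:
        if tables is None:
            continue
        rows.append({**meta, **summarize_run(tables)})
    return pd.DataFrame(rows)
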