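"""The agent-based model proper: world state, agent lifecycle, timestep loop.

Forager groups (agents) enter a ``grid_width x grid_height`` landscape
sequentially: when one steps beyond the grid it is removed together with
everything it carries, and the next agent is placed on a random square.
Each agent-timestep runs four behaviors in a fixed order — resupply
check, scavenge, knap, discard, move — and the run ends once ``n_agents``
have passed through.  "Model year" is the timestep counter; placing an
agent consumes one timestep, so runs with short-lived agents (low mu)
spend proportionally more of their length on placement.

A single seeded RNG stream drives every stochastic choice in a run, so a
config plus its seed replays byte-identically.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from recyclesim.artifacts import (
    NODULE_VOLUME,
    SCHEDULE_UNITS,
    Flake,
    Nodule,
    build_flake_schedule,
)
from recyclesim.config import ConfigError, SimulationConfig

#: Sentinel returned by :func:`move_agent` when the agent leaves the grid.
EXITED = object()

# A nodule's volume in 4%-of-nodule units: remnant core (5 units, never
# flakeable) + the 20 schedule units.  Exact integer volume accounting.
_NODULE_VUNITS = 25


class GridSquare:
    """A landscape cell: an assemblage plus cumulative event counters."""

    __slots__ = ("row", "col", "assemblage", "discard_events",
                 "scavenge_events", "encounters", "retouch_events")

    def __init__(self, row: int, col: int) -> None:
        self.row = row
        self.col = col
        self.assemblage: list = []
        self.discard_events = 0
        self.scavenge_events = 0
        self.encounters = 0
        self.retouch_events = 0


class Agent:
    """A mobile forager group with a technology type and a hand inventory."""

    __slots__ = ("id", "tech_type", "x", "y", "hand")

    def __init__(self, id: int, tech_type: int, x: float, y: float) -> None:
        self.id = id
        self.tech_type = tech_type
        self.x = x
        self.y = y
        self.hand: list = []


class RunState:
    """Mutable state of one model run, with running landscape totals.

    The totals (cortex units, volume units, object/recycled counts,
    occupied-square count) are maintained incrementally on every discard
    and scavenge so the per-timestep model row costs O(1) instead of a
    full landscape scan.
    """

    def __init__(self, config: SimulationConfig, log_events: bool = False) -> None:
        self.config = config
        self.rng = random.Random(config.seed)
        self.grid = [[GridSquare(r, c) for c in range(config.grid_width)]
                     for r in range(config.grid_height)]
        self.active_agent: Agent | None = None
        self.agents_started = 0
        self.agents_completed = 0
        self.model_year = 0
        self.exported_objects: list = []
        self.nodules_introduced = 0
        self._next_object_id = 0
        self._tech_assignments: list[int] = []

        # landscape running totals (discard record only, not hands)
        self.landscape_cortex_units = 0
        self.landscape_volume_units = 0
        self.landscape_objects = 0
        self.landscape_flakes = 0
        self.landscape_nodules = 0
        self.landscape_recycled = 0
        self.n_assemblages = 0

        # cumulative event counters (sums of the square counters)
        self.total_encounters = 0
        self.total_discard_events = 0
        self.total_scavenge_events = 0
        self.total_retouch_events = 0

        # per-year event counters, reset each timestep
        self.year_scavenges = 0
        self.year_discards = 0
        self.year_recycled_created = 0
        self.year_retouches = 0
        self.year_blanks = 0

        self.model_rows: list[dict] = []
        self.square_rows: list[dict] = []
        self.artifacts_mid: pd.DataFrame | None = None

        self.log_events = log_events
        self.event_log: list[tuple] = []

    # -- helpers -------------------------------------------------------

    def new_object_id(self) -> int:
        self._next_object_id += 1
        return self._next_object_id

    def square_at(self, x: float, y: float) -> GridSquare:
        """Cell occupied by a position given in movement units."""
        s = self.config.square_size
        col = min(int(x / s), self.config.grid_width - 1)
        row = min(int(y / s), self.config.grid_height - 1)
        return self.grid[row][col]

    @property
    def current_square(self) -> GridSquare:
        a = self.active_agent
        return self.square_at(a.x, a.y)

    def squares(self):
        for row in self.grid:
            yield from row

    def landscape_objects_iter(self):
        for sq in self.squares():
            yield from sq.assemblage

    def closed_system_objects(self):
        """All objects ever introduced and not exported: landscape + hand."""
        yield from self.landscape_objects_iter()
        if self.active_agent is not None:
            yield from self.active_agent.hand

    def total_system_volume(self) -> float:
        """Volume over landscape, active hand and exported objects."""
        vol = sum(o.volume for o in self.closed_system_objects())
        vol += sum(o.volume for o in self.exported_objects)
        return vol

    def landscape_cortex_ratio(self) -> float:
        """Overall cortex ratio of the discard record (NaN when empty)."""
        if self.landscape_objects == 0:
            return float("nan")
        # obs/exp = (cu/20 * SA) / (vu*0.04 * SA) = 1.25 * cu / vu
        return 1.25 * self.landscape_cortex_units / self.landscape_volume_units

    def landscape_recycling_incidence(self) -> float:
        if self.landscape_objects == 0:
            return 0.0
        return self.landscape_recycled / self.landscape_objects

    # -- totals bookkeeping -------------------------------------------

    def _add_to_landscape(self, obj, square: GridSquare) -> None:
        if not square.assemblage:
            self.n_assemblages += 1
        square.assemblage.append(obj)
        self.landscape_cortex_units += obj.cortex_units
        if obj.kind == "flake":
            self.landscape_flakes += 1
            self.landscape_volume_units += obj.size
        else:
            self.landscape_nodules += 1
            self.landscape_volume_units += _NODULE_VUNITS - obj.removed_units
        self.landscape_objects += 1
        if obj.recycled:
            self.landscape_recycled += 1

    def _remove_from_landscape(self, obj, square: GridSquare) -> None:
        self.landscape_cortex_units -= obj.cortex_units
        if obj.kind == "flake":
            self.landscape_flakes -= 1
            self.landscape_volume_units -= obj.size
        else:
            self.landscape_nodules -= 1
            self.landscape_volume_units -= _NODULE_VUNITS - obj.removed_units
        self.landscape_objects -= 1
        if obj.recycled:
            self.landscape_recycled -= 1


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def draw_step_length(mu: float, u: float) -> float:
    """Invert the power-law step distribution: ``l = u ** (-1/mu)``.

    ``u`` is a uniform draw on (0, 1]; the returned length is always
    >= 1 grid unit.  ``u == 0`` must be resampled by the caller.
    """
    if mu < 1:
        raise ConfigError("mu: must be >= 1")
    if not 0.0 < u <= 1.0:
        raise ValueError("u must lie in (0, 1]; resample u == 0")
    return u ** (-1.0 / mu)


def assign_technology(agent_index: int, overlap: int, rng: random.Random) -> int:
    """Technology signature for a new agent.

    ``overlap == 1``: one of two shared types, drawn uniformly.
    ``overlap == 2``: a type unique to this agent (its ordinal + 1).
    """
    if overlap == 1:
        return rng.randint(1, 2)
    if overlap == 2:
        return agent_index + 1
    raise ConfigError("overlap: must be 1 or 2")


def matches_selection(obj, config: SimulationConfig) -> bool:
    """Does the object match the agent's selection criteria?

    Kind must match the flake/nodule preference; a size preference
    additionally requires flakes of size >= ``min_select_size``.  Size
    preferences never apply to nodules.
    """
    if obj.kind == "flake":
        if not config.flake_preference:
            return False
        if config.size_preference and obj.size < config.min_select_size:
            return False
        return True
    return not config.flake_preference


# ---------------------------------------------------------------------------
# per-timestep behaviors
# ---------------------------------------------------------------------------

def resupply(state: RunState) -> int:
    """Grant fresh nodules iff the agent's hand is empty."""
    agent = state.active_agent
    if agent.hand:
        return 0
    cfg = state.config
    for _ in range(cfg.n_resupply_nodules):
        schedule = build_flake_schedule(cfg.max_flake_size, state.rng)
        agent.hand.append(Nodule(state.new_object_id(), schedule))
        state.nodules_introduced += 1
    return cfg.n_resupply_nodules


def scavenge(state: RunState) -> list:
    """Collect artifacts from the current square's assemblage.

    Matching objects are considered first in random order; non-matching
    objects follow (also in random order) only under non-strict
    selection.  Each candidate is picked up with probability
    ``scavenge_prob`` until the hand reaches ``max_carry``.
    """
    agent = state.active_agent
    square = state.current_square
    if not square.assemblage:
        return []
    cfg = state.config
    rng = state.rng
    matching = []
    others = []
    for obj in square.assemblage:
        (matching if matches_selection(obj, cfg) else others).append(obj)
    rng.shuffle(matching)
    if cfg.strict_selection:
        candidates = matching
    else:
        rng.shuffle(others)
        candidates = matching + others

    collected = []
    room = cfg.max_carry - len(agent.hand)
    p = cfg.scavenge_prob
    for obj in candidates:
        if room <= 0:
            break
        if rng.random() < p:
            collected.append(obj)
            room -= 1
    if not collected:
        return []

    taken = set(id(o) for o in collected)
    square.assemblage = [o for o in square.assemblage if id(o) not in taken]
    for obj in collected:
        state._remove_from_landscape(obj, square)
        agent.hand.append(obj)
    if not square.assemblage:
        state.n_assemblages -= 1
    n = len(collected)
    square.scavenge_events += n
    state.total_scavenge_events += n
    state.year_scavenges += n
    if state.log_events:
        state.event_log.append(
            (state.model_year, "scavenge", square.row, square.col, n))
    return collected


def _do_blank(state: RunState, nodules_avail: list) -> None:
    agent = state.active_agent
    rng = state.rng
    nod = nodules_avail[rng.randrange(len(nodules_avail))]
    size = nod.detach_next()
    was_recycled = nod.recycled
    if nod.first_tech is None:
        nod.first_tech = agent.tech_type
    nod.last_tech = agent.tech_type
    nod._groups.add(agent.id)
    if not was_recycled and nod.recycled:
        state.year_recycled_created += 1
    flake = Flake(state.new_object_id(), size,
                  first_tech=agent.tech_type, last_tech=agent.tech_type)
    flake._groups.add(agent.id)
    agent.hand.append(flake)
    state.year_blanks += 1


def _do_retouch(state: RunState, flakes_avail: list) -> None:
    agent = state.active_agent
    rng = state.rng
    flake = flakes_avail[rng.randrange(len(flakes_avail))]
    was_recycled = flake.recycled
    flake.stage += 1
    flake.last_tech = agent.tech_type
    flake._groups.add(agent.id)
    if not was_recycled and flake.recycled:
        state.year_recycled_created += 1
    square = state.current_square
    square.retouch_events += 1
    state.total_retouch_events += 1
    state.year_retouches += 1
    if state.log_events:
        state.event_log.append(
            (state.model_year, "retouch", square.row, square.col, 1))


def knap(state: RunState) -> str:
    """Produce a blank or retouch a flake, per ``blank_prob``.

    The impossible action falls back to the other; with neither possible
    the timestep's knap is a no-op.  Returns "blank", "retouch" or
    "noop".
    """
    agent = state.active_agent
    cfg = state.config
    rng = state.rng
    want_blank = rng.random() < cfg.blank_prob
    did = "noop"
    for _ in range(cfg.flakes_per_blank_event if want_blank else 1):
        nodules_avail = [o for o in agent.hand
                         if o.kind == "nodule" and o.has_flakes]
        flakes_avail = [o for o in agent.hand if o.kind == "flake"]
        do_blank = want_blank
        if do_blank and not nodules_avail:
            do_blank = False
        if not do_blank and not flakes_avail:
            if nodules_avail:
                do_blank = True
            else:
                break
        if do_blank:
            _do_blank(state, nodules_avail)
            did = "blank" if did in ("noop", "blank") else did
        else:
            _do_retouch(state, flakes_avail)
            did = "retouch"
            break  # only blank production repeats under the multi-flake knob
    return did


def discard(state: RunState) -> list:
    """Drop objects until the hand fits ``max_carry``.

    Non-matching objects are dropped first (uniformly at random among
    them), then matching objects if still over capacity.  Dropped
    objects join the current square's assemblage and keep their original
    year of first discard if they ever had one.
    """
    agent = state.active_agent
    cfg = state.config
    n_drop = len(agent.hand) - cfg.max_carry
    if n_drop <= 0:
        return []
    rng = state.rng
    matching = []
    others = []
    for obj in agent.hand:
        (matching if matches_selection(obj, cfg) else others).append(obj)
    rng.shuffle(others)
    rng.shuffle(matching)
    order = others + matching
    dropped = order[:n_drop]
    agent.hand = order[n_drop:]

    square = state.current_square
    for obj in dropped:
        if obj.year_first_discard is None:
            obj.year_first_discard = state.model_year
        state._add_to_landscape(obj, square)
    square.discard_events += n_drop
    state.total_discard_events += n_drop
    state.year_discards += n_drop
    if state.log_events:
        state.event_log.append(
            (state.model_year, "discard", square.row, square.col, n_drop))
    return dropped


def move_agent(state: RunState):
    """Lévy-walk displacement; returns the new (x, y) or ``EXITED``.

    Heading is uniform over [0, 360) degrees; step length is drawn by
    inverting the power law.  Stepping outside the half-open landscape
    box removes the agent and exports everything it carries.
    """
    agent = state.active_agent
    cfg = state.config
    rng = state.rng
    theta = math.radians(rng.random() * 360.0)
    u = 1.0 - rng.random()  # uniform on (0, 1]
    length = u ** (-1.0 / cfg.mu)
    agent.x += length * math.cos(theta)
    agent.y += length * math.sin(theta)
    s = cfg.square_size
    if not (0.0 <= agent.x < cfg.grid_width * s
            and 0.0 <= agent.y < cfg.grid_height * s):
        state.exported_objects.extend(agent.hand)
        agent.hand = []
        state.active_agent = None
        return EXITED
    square = state.current_square
    square.encounters += 1
    state.total_encounters += 1
    if state.log_events:
        state.event_log.append(
            (state.model_year, "encounter", square.row, square.col, 1))
    return (agent.x, agent.y)


def _place_next_agent(state: RunState) -> Agent:
    """Place the next agent on a uniformly random grid square."""
    cfg = state.config
    rng = state.rng
    idx = state.agents_started
    tech = assign_technology(idx, cfg.overlap, rng)
    col = rng.randrange(cfg.grid_width)
    row = rng.randrange(cfg.grid_height)
    s = cfg.square_size
    agent = Agent(idx, tech, (col + 0.5) * s, (row + 0.5) * s)
    state.active_agent = agent
    state.agents_started += 1
    state._tech_assignments.append(tech)
    square = state.grid[row][col]
    square.encounters += 1
    state.total_encounters += 1
    if state.log_events:
        state.event_log.append(
            (state.model_year, "encounter", row, col, 1))
    return agent


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------

def initialize_run(config: SimulationConfig, log_events: bool = False) -> RunState:
    """Empty landscape, first agent placed, model year 0.

    Agents are initialized with no objects; placing an agent consumes
    one timestep, so the first behavior timestep is model year 1.
    """
    state = RunState(config, log_events=log_events)
    _place_next_agent(state)
    _record_model_row(state)
    return state


def run_timestep(state: RunState) -> RunState:
    """One model year: either place a pending agent, or run the four
    behaviors (resupply check, scavenge, knap, discard, move)."""
    state.model_year += 1
    state.year_scavenges = 0
    state.year_discards = 0
    state.year_recycled_created = 0
    state.year_retouches = 0
    state.year_blanks = 0

    if state.active_agent is None:
        _place_next_agent(state)
    else:
        resupply(state)
        scavenge(state)
        knap(state)
        discard(state)
        result = move_agent(state)
        if result is EXITED:
            state.agents_completed += 1
            cfg = state.config
            mid = (cfg.n_agents + 1) // 2
            if state.artifacts_mid is None and state.agents_completed >= mid:
                state.artifacts_mid = _artifact_table(state)

    _record_model_row(state)
    if state.model_year % state.config.snapshot_interval == 0:
        _record_square_snapshot(state)
    return state


@dataclass
class OutputTables:
    """The three recording levels of one run, as tidy DataFrames."""

    artifacts_mid: pd.DataFrame
    artifacts_final: pd.DataFrame
    squares: pd.DataFrame
    model: pd.DataFrame
    config: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write the tables as CSV files under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts_mid.to_csv(outdir / "artifacts_mid.csv", index=False)
        self.artifacts_final.to_csv(outdir / "artifacts_final.csv", index=False)
        self.squares.to_csv(outdir / "squares.csv", index=False)
        self.model.to_csv(outdir / "model.csv", index=False)
        if self.config:
            import json

            (outdir / "config.json").write_text(
                json.dumps(self.config, indent=2) + "\n")


def run_model(config: SimulationConfig, log_events: bool = False,
              return_state: bool = False):
    """Run the model until all agents have moved through the landscape.

    Returns :class:`OutputTables`; with ``return_state=True`` returns
    ``(tables, final_state)`` for invariant checks and replay.
    """
    state = initialize_run(config, log_events=log_events)
    n = config.n_agents
    while state.agents_completed < n:
        run_timestep(state)
    # final snapshot, if the run did not end exactly on the interval
    if state.model_year % config.snapshot_interval != 0:
        _record_square_snapshot(state)
    artifacts_final = _artifact_table(state)
    if state.artifacts_mid is None:  # pragma: no cover - defensive
        state.artifacts_mid = artifacts_final
    tables = OutputTables(
        artifacts_mid=state.artifacts_mid,
        artifacts_final=artifacts_final,
        squares=pd.DataFrame(state.square_rows, columns=_SQUARE_COLUMNS),
        model=pd.DataFrame(state.model_rows, columns=_MODEL_COLUMNS),
        config=config.to_dict(),
    )
    if return_state:
        return tables, state
    return tables


# ---------------------------------------------------------------------------
# recording (schemas shared with recyclesim.metrics)
# ---------------------------------------------------------------------------

_ARTIFACT_COLUMNS = ["object_kind", "year_first_discard", "stage", "n_groups",
                     "first_tech", "last_tech", "recycled"]

_SQUARE_COLUMNS = ["snapshot_year", "row", "col", "nodule_count",
                   "flake_count", "cortex_ratio", "recycling_incidence",
                   "discard_events", "scavenge_events", "encounters",
                   "retouch_events"]

_MODEL_COLUMNS = ["model_year", "year_scavenge_events", "year_discard_events",
                  "year_recycled_created", "year_retouch_events",
                  "year_blank_events", "recycled_on_landscape",
                  "n_assemblages", "total_encounters", "total_discard_events",
                  "total_retouch_events", "cortex_ratio",
                  "recycling_incidence"]


def _artifact_table(state: RunState) -> pd.DataFrame:
    """Artifact-level table over the current discard record."""
    rows = []
    for obj in state.landscape_objects_iter():
        rows.append({
            "object_kind": obj.kind,
            "year_first_discard": obj.year_first_discard,
            "stage": obj.stage if obj.kind == "flake" else obj.removed_units,
            "n_groups": obj.n_groups,
            "first_tech": obj.first_tech,
            "last_tech": obj.last_tech,
            "recycled": obj.recycled,
        })
    return pd.DataFrame(rows, columns=_ARTIFACT_COLUMNS)


def _record_model_row(state: RunState) -> None:
    from recyclesim.metrics import record_model_row

    state.model_rows.append(record_model_row(state))


def _record_square_snapshot(state: RunState) -> None:
    from recyclesim.metrics import record_square_snapshot

    state.square_rows.extend(record_square_snapshot(state))
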