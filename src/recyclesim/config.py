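"""Run configuration: the full parameter vector for one simulation run.

Every knob of the model lives on :class:`SimulationConfig`; a config plus
a seed fully determines a run.  Configs can be loaded from YAML or JSON
files whose keys are exactly the dataclass fields (unknown keys are
rejected so typos fail loudly).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameter vector for a single model run.

    Parameters
    ----------
    grid_width, grid_height
        Landscape extent in grid cells.
    n_agents
        Number of forager groups that pass through the landscape; the
        run ends when all of them have exited.
    mu
        Lévy-walk exponent (>= 1).  High ``mu`` favours short steps and
        long landscape residence; ``mu`` near 1 favours long steps and
        quick exits.
    overlap
        Technology regime.  1 = two shared technology types assigned at
        random; 2 = a unique technology type per agent.
    scavenge_prob
        Probability of picking up each encountered candidate artifact.
    blank_prob
        Probability that the knapping action of a timestep is blank
        production (detach a flake from a nodule); otherwise retouch.
    flake_preference
        True = agents prefer flakes, False = agents prefer nodules, for
        both scavenging priority and discard retention.
    size_preference, min_select_size
        If ``size_preference`` is set, only flakes of size >=
        ``min_select_size`` match the selection criteria.  Size never
        applies to nodules.
    strict_selection
        If set, agents never scavenge non-matching artifacts.
    max_flake_size
        1 or 2.  With 2, nodule flake schedules mix sizes 1 and 2.
    max_carry
        Hand-inventory capacity enforced at discard.
    n_resupply_nodules
        Fresh nodules granted whenever an agent's hand is empty.
    flakes_per_blank_event
        Flakes detached per blank-production action (default 1).
    snapshot_interval
        Timesteps between grid-square snapshots.
    square_size
        Side length of one grid square in movement units.  Step lengths
        are drawn in movement units with a minimum of 1, so this sets
        how coarse the recording grid is relative to the movement
        scale; 1.0 makes squares and steps commensurate.
    seed
        Seed for the single RNG stream driving the run.
    """

    grid_width: int = 10
    grid_height: int = 10
    n_agents: int = 100
    mu: float = 1.0
    overlap: int = 1
    scavenge_prob: float = 0.5
    blank_prob: float = 0.5
    flake_preference: bool = True
    size_preference: bool = False
    min_select_size: int = 1
    strict_selection: bool = False
    max_flake_size: int = 2
    max_carry: int = 10
    n_resupply_nodules: int = 1
    flakes_per_blank_event: int = 1
    snapshot_interval: int = 300
    square_size: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        def fail(field: str, msg: str) -> None:
            raise ConfigError(f"{field}: {msg}")

        if self.grid_width < 1:
            fail("grid_width", "must be >= 1")
        if self.grid_height < 1:
            fail("grid_height", "must be >= 1")
        if self.n_agents < 1:
            fail("n_agents", "must be >= 1")
        if self.mu < 1:
            fail("mu", "must be >= 1")
        if self.overlap not in (1, 2):
            fail("overlap", "must be 1 (two shared technologies) or 2 (unique)")
        for field in ("scavenge_prob", "blank_prob"):
            p = getattr(self, field)
            if not 0.0 <= p <= 1.0:
                fail(field, "must be a probability in [0, 1]")
        if self.min_select_size < 1:
            fail("min_select_size", "must be >= 1")
        if self.max_flake_size not in (1, 2):
            fail("max_flake_size", "must be 1 or 2")
        if self.max_carry < 1:
            fail("max_carry", "must be >= 1")
        if self.n_resupply_nodules < 1:
            fail("n_resupply_nodules", "must be >= 1")
        if self.flakes_per_blank_event < 1:
            fail("flakes_per_blank_event", "must be >= 1")
        if self.snapshot_interval < 1:
            fail("snapshot_interval", "must be >= 1")
        if self.square_size <= 0:
            fail("square_size", "must be > 0")

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file.

    Unknown keys raise :class:`ConfigError` rather than being ignored.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)
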