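"""Lithic objects: icosahedral nodules and the flakes detached from them.

A nodule is modelled as a 20-sided object whose faces are removable
flakes.  Size units partition the nodule: the flake schedule (sizes of
the flakes still attached) plus the units already removed always sum to
20.  Cortex accounting follows from that partition: a fresh nodule is
fully cortical with surface area 11091.8 square units, each size unit
carries one twentieth of that cortex, and flakes are fully cortical
objects.  Volume accounting reserves a remnant core: each size unit is
4% of the 100000 cubic-unit starting volume, so a fully reduced nodule
retains 20% of its volume with no cortex.
"""

from __future__ import annotations

import random

NODULE_SURFACE_AREA = 11091.8  # fresh-nodule cortical surface, square units
NODULE_VOLUME = 100_000.0  # fresh-nodule volume, cubic units
SCHEDULE_UNITS = 20  # size units per nodule
_UNIT_FRACTION_VOL = 0.04  # volume fraction per size unit


class Flake:
    """A flake detached from a nodule; retouchable, fully cortical.

    ``stage`` counts retouch actions.  ``first_tech`` is the technology
    signature of the agent that detached the flake, ``last_tech`` that of
    the most recent knapper; the flake is identifiably recycled when the
    two differ.
    """

    __slots__ = ("id", "size", "stage", "first_tech", "last_tech",
                 "_groups", "year_first_discard")

    def __init__(self, id: int, size: int, first_tech: int | None = None,
                 last_tech: int | None = None) -> None:
        self.id = id
        self.size = size
        self.stage = 0
        self.first_tech = first_tech
        self.last_tech = last_tech
        self._groups: set[int] = set()
        self.year_first_discard: int | None = None

    kind = "flake"

    @property
    def n_groups(self) -> int:
        """Distinct agents that have produced or retouched this flake."""
        return len(self._groups)

    @property
    def cortical_area(self) -> float:
        return (self.size / SCHEDULE_UNITS) * NODULE_SURFACE_AREA

    @property
    def volume(self) -> float:
        return self.size * _UNIT_FRACTION_VOL * NODULE_VOLUME

    @property
    def cortex_units(self) -> int:
        return self.size

    @property
    def recycled(self) -> bool:
        return (self.first_tech is not None and self.last_tech is not None
                and self.first_tech != self.last_tech)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Flake(id={self.id}, size={self.size}, stage={self.stage}, "
                f"first={self.first_tech}, last={self.last_tech})")


class Nodule:
    """A raw-material block holding a schedule of removable flakes."""

    __slots__ = ("id", "flake_schedule", "removed_units", "first_tech",
                 "last_tech", "_groups", "year_first_discard")

    def __init__(self, id: int, flake_schedule: list[int]) -> None:
        if sum(flake_schedule) != SCHEDULE_UNITS:
            raise ValueError("flake schedule of a fresh nodule must sum to "
                             f"{SCHEDULE_UNITS} size units")
        self.id = id
        self.flake_schedule = list(flake_schedule)
        self.removed_units = 0
        self.first_tech: int | None = None
        self.last_tech: int | None = None
        self._groups: set[int] = set()
        self.year_first_discard: int | None = None

    kind = "nodule"

    @property
    def n_groups(self) -> int:
        """Distinct agents that have removed blanks from this nodule."""
        return len(self._groups)

    @property
    def remaining_units(self) -> int:
        return SCHEDULE_UNITS - self.removed_units

    @property
    def cortical_area(self) -> float:
        return (self.remaining_units / SCHEDULE_UNITS) * NODULE_SURFACE_AREA

    @property
    def volume(self) -> float:
        return NODULE_VOLUME * (1.0 - _UNIT_FRACTION_VOL * self.removed_units)

    @property
    def cortex_units(self) -> int:
        return self.remaining_units

    @property
    def recycled(self) -> bool:
        return (self.first_tech is not None and self.last_tech is not None
                and self.first_tech != self.last_tech)

    @property
    def has_flakes(self) -> bool:
        return bool(self.flake_schedule)

    def detach_next(self) -> int:
        """Remove the next scheduled flake; returns its size."""
        size = self.flake_schedule.pop(0)
        self.removed_units += size
        return size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Nodule(id={self.id}, remaining={self.remaining_units}, "
                f"first={self.first_tech}, last={self.last_tech})")


def build_flake_schedule(max_flake_size: int, rng: random.Random) -> list[int]:
    """Draw the flake schedule for a fresh nodule.

    With ``max_flake_size == 1`` the nodule is 20 size-1 flakes.  With 2,
    sizes are drawn uniformly from {1, 2} slot by slot until the 20 size
    units are consumed, with a trailing size-1 flake if one unit remains.
    """
    if max_flake_size == 1:
        return [1] * SCHEDULE_UNITS
    schedule: list[int] = []
    remaining = SCHEDULE_UNITS
    while remaining > 0:
        size = rng.randint(1, 2) if remaining >= 2 else 1
        schedule.append(size)
        remaining -= size
    return schedule
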