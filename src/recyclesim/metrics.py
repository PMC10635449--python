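"""Assemblage-level metrics and the three-level output recorder.

Cortex ratio follows the icosahedron scheme: observed cortical surface
area of an assemblage divided by the surface area expected from its
total stone volume.  Each of a nodule's 20 size units carries 1/20 of
the 11091.8-square-unit starting cortex and 4% of the 100000-cubic-unit
starting volume; the 20% remnant core volume never carries cortex, which
is what pushes the ratio above 1 when non-cortical elements (reduced
nodules) are removed from an assemblage and below 1 when the fully
cortical flakes are removed.

Recycling incidence is the share of objects (flakes and nodules) whose
first and last technology signatures differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from recyclesim.artifacts import NODULE_SURFACE_AREA, NODULE_VOLUME, SCHEDULE_UNITS


@dataclass(frozen=True)
class AssemblageSummary:
    nodule_count: int
    flake_count: int
    observed_cortical_sa: float
    total_volume: float
    expected_cortical_sa: float
    cortex_ratio: float
    recycled_count: int
    recycling_incidence: float


def assemblage_summary(objects) -> AssemblageSummary:
    """Full cortex and recycling accounting for a collection of objects."""
    objects = list(objects)
    nodules = sum(1 for o in objects if o.kind == "nodule")
    flakes = len(objects) - nodules
    observed = sum(o.cortical_area for o in objects)
    volume = sum(o.volume for o in objects)
    expected = (volume / NODULE_VOLUME) * NODULE_SURFACE_AREA
    if not objects:
        ratio = float("nan")
    else:
        ratio = observed / expected
    recycled = sum(1 for o in objects if o.recycled)
    incidence = recycled / len(objects) if objects else 0.0
    return AssemblageSummary(
        nodule_count=nodules,
        flake_count=flakes,
        observed_cortical_sa=observed,
        total_volume=volume,
        expected_cortical_sa=expected,
        cortex_ratio=ratio,
        recycled_count=recycled,
        recycling_incidence=incidence,
    )


def cortex_ratio(objects) -> float:
    """Observed / expected cortical surface area; NaN for an empty set."""
    return assemblage_summary(objects).cortex_ratio


def recycling_incidence(objects) -> float:
    """Share of objects with differing first/last technology; 0 if empty."""
    return assemblage_summary(objects).recycling_incidence


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

def record_square_snapshot(state) -> list[dict]:
    """One row per grid square; counters cumulative since run start."""
    rows = []
    year = state.model_year
    for sq in state.squares():
        summ = assemblage_summary(sq.assemblage)
        rows.append({
            "snapshot_year": year,
            "row": sq.row,
            "col": sq.col,
            "nodule_count": summ.nodule_count,
            "flake_count": summ.flake_count,
            "cortex_ratio": summ.cortex_ratio,
            "recycling_incidence": summ.recycling_incidence,
            "discard_events": sq.discard_events,
            "scavenge_events": sq.scavenge_events,
            "encounters": sq.encounters,
            "retouch_events": sq.retouch_events,
        })
    return rows


def record_model_row(state) -> dict:
    """The per-timestep model-level series (twelve fields + year)."""
    return {
        "model_year": state.model_year,
        "year_scavenge_events": state.year_scavenges,
        "year_discard_events": state.year_discards,
        "year_recycled_created": state.year_recycled_created,
        "year_retouch_events": state.year_retouches,
        "year_blank_events": state.year_blanks,
        "recycled_on_landscape": state.landscape_recycled,
        "n_assemblages": state.n_assemblages,
        "total_encounters": state.total_encounters,
        "total_discard_events": state.total_discard_events,
        "total_retouch_events": state.total_retouch_events,
        "cortex_ratio": state.landscape_cortex_ratio(),
        "recycling_incidence": state.landscape_recycling_incidence(),
    }
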