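# Methods

## The model

`recyclesim` is an agent-based model of archaeological record formation
through stone-tool scavenging, recycling and discard on a surface
landscape.  The landscape is a rectangular grid (default 10 × 10
squares) with no geology: every discarded artifact stays exposed on the
surface of its square indefinitely, so length of exposure equals time
since first discard.

Forager groups ("agents") pass through the landscape **sequentially**:
exactly one agent is active at a time, and when it steps beyond the
grid it is removed together with everything it carries, after which the
next agent is placed on a uniformly random square.  Placing an agent
consumes one timestep ("model year"); a run ends when `n_agents` groups
have moved through.  Run length is therefore emergent — it is the sum
of every agent's residence time plus one placement step per agent.

Each agent-timestep executes four behaviors in a fixed order:

1. **Resupply check** — an empty-handed agent receives
   `n_resupply_nodules` fresh nodules (local raw-material
   availability; no travel to sources is modelled).
2. **Scavenge** — each artifact in the occupied square's assemblage is
   considered in priority order (artifacts matching the agent's
   selection criteria first, in random order; non-matching artifacts
   after, and only under non-strict selection) and collected with
   probability `scavenge_prob` per artifact until the hand holds
   `max_carry` objects.
3. **Knap** — with probability `blank_prob` the agent detaches the
   next flake from a random nodule in hand (blank production);
   otherwise it retouches a random flake in hand (stage + 1).  An
   impossible draw falls back to the other action.
4. **Discard, then move** — objects beyond `max_carry` are dropped
   into the current square (non-matching objects first, uniformly at
   random), then the agent takes a Lévy-walk step: heading uniform on
   [0°, 360°), length `l = u^(-1/mu)` with `u ~ Uniform(0, 1]`, so
   `l >= 1` movement unit always.

### Lithics and cortex accounting

A nodule is a 20-sided block whose faces are removable flakes.  Its
*flake schedule* (the sizes of the flakes still attached, each 1 or 2
size units) plus the units already removed always sum to 20.  A fresh
nodule is fully cortical with surface area 11091.8 square units and
volume 100000 cubic units; each size unit carries 1/20 of the cortex
and 4% of the volume, leaving a 20% remnant core volume with no cortex
after full reduction.  Flakes are fully cortical.  The **cortex
ratio** of an assemblage is observed cortical surface area divided by
the surface area expected from its total volume
(`expected = volume / 100000 × 11091.8`).  Two exact consequences are
used as invariants throughout the test suite: total volume is conserved
(landscape + hand + exported = 100000 × nodules introduced) and the
cortex ratio of the closed system is identically 1; deviations from 1
in an assemblage therefore measure net artifact transport, not
numerical drift.  An assemblage of flakes only has cortex ratio exactly
1.25 (each size unit carries 1/20 of the cortex but only 1/25 of the
cortex-bearing volume).

### Technology signatures and recycling

Every object records the technology type of the first agent to reduce
it and of the most recent knapper.  An object is **identifiably
recycled** when the two differ.  With `overlap = 1` agents draw one of
two shared technology types, so recycling by a like-typed group leaves
no signature; with `overlap = 2` every agent has a unique type and all
cross-group reworking is identifiable.  Fresh, never-knapped nodules
have unset signatures and are never recycled or recyclable until first
reduction.  The per-year "recycled objects created" series counts
false→true transitions of the recycled flag (an object re-knapped by
its original technology can transition back, and would be counted again
on a later true transition).

### Movement scale (`square_size`)

Step lengths are drawn in *movement units* with a minimum of 1, while
behaviors and recording happen on *grid squares*.  `square_size` sets
the side of a square in movement units.  The default of 8 makes the
recording grid coarser than the movement grain, which reproduces the
intended recording cadence: with μ = 3 an agent resides a few hundred
timesteps, a 100-agent run lasts on the order of 3 × 10⁴ model years,
and square snapshots every 300 timesteps yield on the order of 100
landscape snapshots per run.  Setting `square_size = 1` makes squares
and steps commensurate (agents then cross a 10 × 10 landscape in a
handful of steps), which the geometric unit tests use.  μ controls
residence: μ near 1 produces frequent long steps and quick, linear
exits; μ = 3 produces tortuous, redundant paths.

## Parameters

| field | default | meaning |
|---|---|---|
| `grid_width`, `grid_height` | 10, 10 | landscape extent, squares |
| `square_size` | 8.0 | square side, movement units |
| `n_agents` | 100 | groups per run (occupational intensity) |
| `mu` | 1.0 | Lévy exponent, ≥ 1 (swept over 1, 2, 3) |
| `overlap` | 1 | 1 = two shared technologies, 2 = unique per agent |
| `scavenge_prob` | 0.5 | pickup probability per encountered artifact |
| `blank_prob` | 0.5 | blank production vs retouch |
| `flake_preference` | True | prefer flakes (False = nodules) |
| `size_preference`, `min_select_size` | False, 1 | flake-size criterion (flakes only) |
| `strict_selection` | False | never collect non-matching artifacts |
| `max_flake_size` | 2 | nodule schedules mix sizes 1 and 2 |
| `max_carry` | 10 | hand capacity enforced at discard |
| `n_resupply_nodules` | 1 | nodules granted when empty-handed |
| `flakes_per_blank_event` | 1 | flakes detached per blank action |
| `snapshot_interval` | 300 | timesteps between square snapshots |

`max_carry`, `n_resupply_nodules` and `flakes_per_blank_event` are
behavioral-capacity assumptions (the published experiments do not state
them); they are exposed as first-class parameters with fixed documented
defaults.  Scavenging applies the pickup probability per artifact, not
per visit.  The default sweep grid crosses `scavenge_prob` ∈
{0.25, 0.5, 0.75, 1.0}, `blank_prob` ∈ {0.25, 0.5, 0.75}, μ ∈ {1, 2, 3},
`n_agents` ∈ {100, 200}, `overlap` ∈ {1, 2} and all selection-flag
combinations (a size preference is inert under a nodule preference and
is collapsed, leaving six selection cells and 864 combinations), with
50 replicates by default and a documented seed schedule
(`base_seed + 10007 × combination + replicate`) so any published run is
replayable in isolation.

## Output recording

Three levels, all plain CSV:

- **Artifacts** (`artifacts_mid.csv` at the timestep when agent
  ⌈n/2⌉ exits, `artifacts_final.csv` at run end): kind, year of first
  discard, stage (retouch count for flakes, removed units for nodules),
  number of distinct groups, first/last technology, recycled flag —
  for every object in the discard record.
- **Squares** (`squares.csv`, every `snapshot_interval` timesteps plus
  a final snapshot): per-square nodule/flake counts, cortex ratio
  (missing when empty, to avoid biasing dispersion statistics),
  recycling incidence (0 when empty), and the four cumulative event
  counters (discards by object, scavenges by object, encounters per
  occupation including placement, retouches).
- **Model** (`model.csv`, every timestep): five per-year event series
  (scavenges, discards, recycled-created, retouches, blanks) and seven
  landscape totals (recycled objects on landscape, occupied squares,
  cumulative encounters/discards/retouches, overall cortex ratio and
  recycling incidence over the discard record — objects in the active
  agent's hand are excluded).

## Statistics

- **COV** = sample SD / mean (missing for zero mean, with a warning).
- **Skewness** = m₃ / m₂^{3/2}, the unadjusted moment coefficient; a
  negative skew of first-discard years marks an assemblage dominated by
  older artifacts.
- **Exposure test**: one-sided Wilcoxon rank-sum of the alternative
  that recycled artifacts have earlier first-discard years; exact
  enumeration for tie-free samples up to n = 50, otherwise the normal
  approximation with continuity and tie correction.
- **Spearman's ρ** with average ranks for ties, computed per grid
  square across runs.
- **Local G**: Getis-Ord Gi with binary queen-contiguity weights, the
  focal cell excluded from its own neighborhood (the statistic compares
  a cell's neighbors to the rest of the landscape), standardized
  analytically under the randomization null using all-but-focal
  moments.  Edge and corner cells use their 5 or 3 available
  neighbors; a constant field is defined as all zeros; missing cells
  are excluded and returned missing.
- **Hotspots**: cells whose local G exceeds the mean + 2 SD of the
  local G values themselves (one-sided; flags are invariant to constant
  shifts of the field).  Overlap is the count of cells flagged in two
  masks.

## Scaled-down acceptance experiment

The published full-scale experiment is 50 replicates of every
combination.  The acceptance suite and `scripts/acceptance.py` run the
complete 864-combination grid at **2 replicates** (1,728 runs, minutes
on one CPU), which is sufficient for the ordering and directional
patterns: recycling incidence the most landscape-variable output and
its COV decreasing with μ and agent count, nodule counts more variable
than flake counts, cortex ratios least variable, behavioral-event COVs
in the full-scale band, recycled artifacts significantly older in the
large majority of non-strict parameter sets, and
recycling-incidence/scavenging hotspot overlap below 1% of the
landscape.  Absolute magnitudes of some dispersion statistics sit above
the full-scale means: the discard record here is sparser than in the
original experiments (whose exact carrying-capacity and resupply values
are unpublished), and emptier squares mechanically inflate
cross-landscape COVs and thin the local-G hotspot tails.  The
corresponding magnitude checks are asserted at their stated tolerances
and report this discrepancy as a known limitation.

## Numerical and design notes

- One RNG stream (`random.Random(seed)`) drives every stochastic choice
  of a run; ties (which nodule to knap, which object to drop) are
  broken by uniform draws from the same stream, so a config plus seed
  replays byte-identically and sweep results are independent of
  execution order and process count.
- Positions are continuous; the occupied square is the floor of the
  position divided by `square_size`; exit is any coordinate outside the
  half-open landscape box.  Exported objects (carried out by exiting
  agents) never enter the discard record.
- Volume bookkeeping is exact integer arithmetic in 4%-units
  internally; landscape totals are maintained incrementally so the
  per-timestep model row is O(1).
- Empty-assemblage conventions: cortex ratio missing, recycling
  incidence 0.
- The landscape-level cortex ratio and recycling incidence cover the
  discard record only (not the active agent's hand).

## What the generator does and does not emulate

The model produces surface palimpsests formed by mobile groups with
local raw-material supply, probabilistic scavenging and
capacity-limited discard.  It does not simulate geological burial or
exposure events, artifact use-life limits, tool typology,
raw-material sourcing distances, or simultaneous agents; technology
signatures are perfectly observable, unlike real double-patina
evidence, so "identifiably recycled" here is an upper bound on what an
archaeologist could recognize.  Passing tests therefore validate the
record-formation logic and its statistical signatures under these
idealizations, not the richness of any real surface record.
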