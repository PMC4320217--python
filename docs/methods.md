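# Methods

`antbridge` simulates a colony of army-ant-like agents foraging on a bounded
100×100 cell lattice. The scientific content is (i) a two-layer pheromone
field with decay, diffusion, and ground→space evaporation; (ii) a
three-state agent model (Search / Return / Altruism) in which crowding at an
impassable ditch recruits ants into living chains that bridge it; and (iii)
probability models that couple chain stability to chain size and local
pheromone. This note records the model, its assumptions, the defaults, and
the places where the design was genuinely open.

## World geometry

Cells are `(x, y)` with x rightward and y downward. Distance is the
Chebyshev metric — orthogonal *and* diagonal neighbours are 1 *Distance*
away — so perception and movement act on Moore neighbourhoods.

The default arena places three 3-cell-wide "bars" (ditches): `leftbar`
(columns 30–32, rows 30–69), `rightbar` (columns 70–72, rows 30–69) and
`centerbar` (rows 70–72, columns 30–72). Published corner pairs such as
(30, 30)–(33, 70) are read half-open on the max edge so each bar blocks
exactly 3 cells across, matching its stated width. The nest is the interior
rectangle (columns 33–69, rows 30–69).

Those three bars alone leave the nest open toward the top of the grid, and
the arena would not split into the "inner part" and "outer part" that the
scenario calls for. The default environment therefore closes the enclosure
with a fourth band (`topbar`, rows 27–29, columns 30–72), also a 3-wide
ditch, so every exit from the nest is a ditch crossing; `close_top=False`
restores the literal three-bar layout, in which a long detour over the top
of the grid exists. All simulation presets use the sealed variant.

Three 8×8 feeding spots sit centred in the outer strips: B across the left
ditch, C across the right ditch, A below the center ditch. The source
figures show the layout only pictorially; these rectangles are package
defaults and fully config-overridable. Spot food is an integer number of
units; a spot with no food left reverts to open ground.

## Pheromone

Two non-negative scalar grids. Agents deposit on the **ground** layer; only
the **space** (airborne) layer is perceived. Per tick, after all agents
act:

1. diffusion–decay of space:
   `space' = r_A·s + r_B·(Σ₄ orth − 4s) + r_C·(Σ₄ diag − 4s)`,
   applied synchronously from the tick-t snapshot, out-of-grid neighbours
   contributing 0 (absorbing edges), negative results clipped to 0 and
   counted (`clip_events`; never triggered at the default rates, for which
   `r_A − 4r_B − 4r_C = 0.576 > 0`);
2. evaporation exchange: `space += r_e·ground; ground −= r_e·ground`.

Defaults `r_A : r_B : r_C = 0.788 : 0.043 : 0.010` and `r_e = 0.05`. With
the eight neighbour weights these rates sum to exactly 1, which would make
a redistribute-to-neighbours kernel mass-conserving; the literal
decay+Laplacian form above is the default, and the conservative variant is
available as `pheromone.kernel: conservative`.

Deposits: `deposit_ground = 1.0` per depositing agent per tick, halved
after a diagonal move (`diagonal_deposit_factor = 0.5`) because diagonally
scattered pheromone is diminished relative to orthogonal moves. Major ants
deposit every tick wherever they walk; Minor ants deposit only while
carrying food home (a config flag lets searching Minors deposit too,
default off). The magnitudes are package defaults — the source material
states the behaviour but not the numbers.

## Agents

Castes: 3 **Major** ants roam by biased random walk and scatter pheromone
broadly (they ignore pheromone themselves and never join chains by
default); **Minor** ants forage, follow airborne pheromone, carry food, and
form chains.

**Search.** In order: (1) food within 1 Distance → take one unit, switch to
Return; (2–4) if at least one *active* (non-Altruism) agent is within 2
Distances and a ditch cell is within 1 Distance → enter the chain
(Altruism); (5) Minors: if any free neighbouring cell carries airborne
pheromone, move to a neighbour with probability proportional to its space
level (uniform fallback when all are zero); (6) otherwise a biased random
walk: a drawn direction other than the current heading is accepted with
probability `alpha` (default 0.5), blocked or rejected draws are redrawn, a
fully surrounded ant waits.

**Return.** On a nest cell: deliver, resume Search. Near a ditch (within 1
Distance): fall back to the random walk — this is what carries ants across
bridges, since the homeward-greedy rule would pin them against the ditch
edge. Otherwise: step to a free neighbour strictly closer (Chebyshev) to
the nest rectangle, ties broken uniformly; wait if blocked.

**Altruism.** A chain member holds its post while at least `n = 2` active
agents are within 2 Distances, rolling the leave dice each tick; it leaves
outright when traffic drops below `n`. The leave probability is
`P = a / (1 + b·Xi²)` with `b = min(eta·log(space+1) + eps, 1)`: `a = 0.4`
(spontaneous leave rate), `eta = 0.1`, `eps = 0.1` (declared defaults for
the unprinted coupling constants), `Xi` the size of the member's chain and
`space` the airborne level over it. Well-scented bridges under traffic are
therefore nearly permanent; abandoned, unscented chains dissolve in a few
ticks. Leaving means stepping to any free position within 1 Distance —
open ground *or the back of a neighbouring chain member* (the ant climbs
onto the bridge and walks off as an ordinary walker). Without the
climb-out rule the middle cell of a 3-wide ditch would be a one-way trap:
a member there never has open ground within reach, and every bar would
accumulate permanent residents. A member whose back currently carries a
walker is load-bearing and does not leave.

Two interpretation points deserve emphasis, both chosen after the
behavioural account of bridges as congestion-driven structures:

* **Perception counts active ants.** The crowding that triggers chain
  entry, and the traffic that keeps members holding, count only
  non-Altruism agents. Chain members are part of the terrain; if they
  counted, an ant leaving a chain would always re-satisfy the entry
  condition one step later and be re-absorbed, and the colony provably
  collapses into a single frozen chain along the ditch walls.
* **Entry placement.** A recruit steps onto a free ditch cell within 1
  Distance, preferring one adjacent to an existing chain so chains grow
  contiguously across the 3-cell band; walkers standing on a bridge can be
  recruited to extend it to the far side.

The reference aggregation models — entry `Pe = Ce0 + Ce1·Xi/(Ce2+Xi)`
(plateau `Ce0+Ce1`), exit `Pl = Cs0 + Cs1/(Cs2+Xi^ν)` — are implemented
and validated but not used by the default schedule, which enters by the
crowding condition and leaves by the pheromone-coupled `P` above;
`behavior.use_lioni_entry` switches the entry gate on. `entry_mode:
model2` replaces the crowding trigger with a pheromone threshold.

**Occupancy.** At most one walker per open cell. A ditch cell may hold one
chain member plus at most one walker crossing on its back; an empty ditch
cell is impassable.

## Schedule

Per tick: agents act once each in a freshly shuffled order (deposits
applied immediately); chains are rebuilt as 1-Distance connected components
of Altruism agents (a chain's id is its smallest member id); space
diffusion; evaporation exchange; metrics record. All randomness flows from
one `numpy` PCG64 generator seeded from the scenario seed; identical
config+seed reproduces runs bitwise. Sweep trials draw their seeds from
`SeedSequence([master, count_index, trial])` so any single trial can be
re-run in isolation.

## Scenarios and metrics

Presets `Env 1-1 … 1-4` (3 Major + 100 Minor) and `Env 2-1 … 2-4`
(3 Major + 50 Minor) with spot-food ratios A:B:C ∈ {2:1:1, 1:2:1, 1:1:2,
4:2:1}. Food is `base_food_units` (default 100) per ratio unit — only the
ratios are published. Runs stop at `max_ticks` (default 10,000) or when
every spot is empty and all cargo delivered.

Per-tick metrics: agents per area (A/B/C/nest/other), remaining and
delivered food per spot, chain sizes, per-ditch bridge flags, carried
units. *Areas* are the spot rectangles dilated by 10 cells, which makes
each area the middle band of its outer strip; the published curves count
"agents in each area" without defining extents, so the margin is a config
default. *Bridge* detection: a connected chain component occupying ditch
cells whose ends touch traversable ground on both sides of the band's
short axis. *Groups*: connected components of non-nest agents under
2-Distance adjacency; components with ≥ 10 members count as groups
(N_Group, mean size N_AgentOfGroup, leftovers N_Others); windowed
summaries report the modal per-tick group count over ticks with food
remaining. No grouping algorithm is published; these defaults are recorded
in every summary.

## What the simulations show (and what they do not)

With the defaults above, the characteristic collective behaviours emerge:
a lone ant can never cross a ditch, while a few dozen ants bridge it and
deliver food; 100-Minor colonies split into concurrent search parties in
different areas; 50-Minor colonies process areas one at a time. These are
emergent, stochastic outcomes verified over seed batches, not fitted
curves. Quantitative trajectories (tick-by-tick occupancy, depletion
times) depend on constants the source never printed (`alpha`, `eta`,
`eps`, deposit sizes, spot geometry, run length) and are therefore not
reproduced numerically, only qualitatively.

Test and demonstration runs use scaled-down problem sizes — thousands of
ticks and a handful of food units per ratio unit — chosen so the emergent
behaviours have time to ignite (trail formation typically takes 2–5k
ticks) while a full seed batch stays cheap; the mechanics are identical at
larger food stocks, only the depletion phase lengthens.

## Known limitations

* A bridge can strand a crossing walker if the chain dissolves around its
  support while it stands mid-ditch; the load-bearing rule (a mounted
  member never leaves) makes this rare but a two-ant deadlock
  (walker + its support) remains possible in principle.
* Return-state ants near a ditch random-walk rather than path-plan; with
  no bridge nearby they jitter at the wall until the trail they deposit
  recruits builders. This is the intended self-organising "doorway"
  mechanism, but it makes homing times heavy-tailed.
* Chains form on any ditch, including the sealing band above the nest,
  where they are useless for foraging; they dissolve by the same traffic
  rule.
* The group-detection defaults (radius 2, min size 10) are one reasonable
  operationalisation of "group"; the published tables used an unspecified
  procedure, so absolute group counts should be compared loosely.
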