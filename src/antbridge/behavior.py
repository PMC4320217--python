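"""Agent behaviour: the Search/Return/Altruism state machine and chain models.

Two castes share one body plan but differ in role: *Major* ants roam the
whole arena scattering pheromone; *Minor* ants forage, follow airborne
pheromone, carry food home, and — when crowded at a ditch — enter the
*Altruism* state, parking themselves on ditch cells so that nestmates can
walk over their backs (a living bridge).

Chain membership is governed by three probability models:

* entering (reference aggregation model):  Pe = Ce0 + Ce1*Xi / (Ce2 + Xi)
* leaving (reference model):               Pl = Cs0 + Cs1 / (Cs2 + Xi**nu)
* leaving (pheromone-coupled, the default used in simulation):
      Pi = a / (1 + b * Xi**2),   b = min(eta*log(space + 1) + eps, 1)

where Xi is the size of chain i and ``space`` the airborne pheromone level
over the ant.  The default runs enter chains by the crowding condition
(another agent within 2 Distances and a ditch within 1) and leave by Pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .environment import CellClass, GridEnvironment, chebyshev_distance

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimState

__all__ = [
    "Caste",
    "AntState",
    "Ant",
    "Chain",
    "BehaviorParams",
    "ChainEntryModel",
    "ChainExitModel",
    "LeaveModel",
    "prob_enter_chain",
    "prob_leave_chain_lioni",
    "prob_leave_chain_pheromone",
    "search_step",
    "return_step",
    "altruism_step",
    "pheromone_guided_move",
    "rebuild_chains",
    "is_traversable",
]

Cell = tuple[int, int]

#: The 8 unit moves of the Moore neighbourhood (1 Distance each).
DIRS8: tuple[Cell, ...] = ((-1, -1), (0, -1), (1, -1),
                           (-1, 0), (1, 0),
                           (-1, 1), (0, 1), (1, 1))


class Caste(Enum):
    MAJOR = "major"
    MINOR = "minor"


class AntState(Enum):
    SEARCH = "search"
    RETURN = "return"
    ALTRUISM = "altruism"


@dataclass(slots=True)
class Ant:
    """One agent.

    ``heading`` is the direction of the last accepted move; the random-walk
    rule prefers continuing straight and accepts a turned direction only
    with probability ``alpha``.
    """

    id: int
    caste: Caste
    pos: Cell
    state: AntState = AntState.SEARCH
    carrying: bool = False
    cargo_from: Optional[str] = None
    chain_id: Optional[int] = None
    heading: Optional[Cell] = None


@dataclass
class Chain:
    """A maximal 1-Distance-connected set of Altruism-state agents."""

    id: int
    members: set[int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class BehaviorParams:
    """Perception radii, crowding threshold and movement parameters.

    n : number of agents that must remain within ``agent_radius`` for a
        chain member to stay put without rolling the leave dice (default 2)
    alpha : probability of accepting a non-straight direction in the
        random walk (declared default 0.5)
    entry_mode : 'model1' (crowding condition) or 'model2' (airborne
        pheromone above ``model2_threshold``)
    use_lioni_entry : gate chain entry by the reference entering
        probability Pe (off by default; the simulated runs enter by
        condition and leave by the pheromone-coupled model)
    majors_form_chains : whether Major ants may enter the Altruism state
    minor_deposit_in_search : whether searching Minors lay pheromone
    """

    n: int = 2
    alpha: float = 0.5
    food_radius: int = 1
    pheromone_radius: int = 2
    agent_radius: int = 2
    ditch_radius: int = 1
    entry_mode: str = "model1"
    model2_threshold: float = 1.0
    use_lioni_entry: bool = False
    majors_form_chains: bool = False
    minor_deposit_in_search: bool = False
    max_direction_draws: int = 12

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.entry_mode not in ("model1", "model2"):
            raise ValueError(f"unknown entry_mode {self.entry_mode!r}")


class ModelConfigurationError(ValueError):
    """Chain-model parameters that cannot yield probabilities in [0, 1]."""


@dataclass
class ChainEntryModel:
    """Saturating entry probability Pe = Ce0 + Ce1*Xi/(Ce2 + Xi)."""

    Ce0: float = 0.1
    Ce1: float = 0.6
    Ce2: float = 4.0

    def __post_init__(self) -> None:
        if min(self.Ce0, self.Ce1) < 0 or self.Ce2 <= 0:
            raise ModelConfigurationError("Ce0, Ce1 >= 0 and Ce2 > 0 required")
        if self.Ce0 + self.Ce1 > 1.0 + 1e-12:
            raise ModelConfigurationError(
                f"plateau Ce0+Ce1={self.Ce0 + self.Ce1} exceeds 1")


@dataclass
class ChainExitModel:
    """Decreasing exit probability Pl = Cs0 + Cs1/(Cs2 + Xi**nu)."""

    Cs0: float = 0.05
    Cs1: float = 0.9
    Cs2: float = 1.0
    nu: float = 2.0

    def __post_init__(self) -> None:
        if min(self.Cs0, self.Cs1) < 0 or self.Cs2 <= 0 or self.nu <= 0:
            raise ModelConfigurationError("Cs0, Cs1 >= 0 and Cs2, nu > 0 required")
        peak = self.Cs0 + self.Cs1 / self.Cs2  # maximum, attained at Xi = 0
        if peak > 1.0 + 1e-12:
            raise ModelConfigurationError(
                f"Pl at Xi=0 is {peak}, outside [0, 1]")


@dataclass
class LeaveModel:
    """Pheromone-coupled leave probability Pi = a/(1 + b*Xi^2).

    ``a`` is the spontaneous leave probability regardless of nestmates;
    ``b`` couples chain stability to the airborne pheromone over the ant:
    b = min(eta*log(space + 1) + eps, 1), so well-scented bridges persist.
    """

    a: float = 0.4
    eta: float = 0.1
    eps: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ModelConfigurationError("a must be in [0, 1]")
        if self.eta < 0 or self.eps < 0:
            raise ModelConfigurationError("eta, eps must be non-negative")


def prob_enter_chain(model: ChainEntryModel, Xi: float) -> float:
    """Probability of joining a chain of size ``Xi`` (saturates at Ce0+Ce1)."""
    if Xi < 0:
        raise ValueError("Xi must be >= 0")
    return model.Ce0 + model.Ce1 * Xi / (model.Ce2 + Xi)


def prob_leave_chain_lioni(model: ChainExitModel, Xi: float) -> float:
    """Reference leave probability, decreasing in chain size toward Cs0."""
    if Xi < 0:
        raise ValueError("Xi must be >= 0")
    return model.Cs0 + model.Cs1 / (model.Cs2 + Xi ** model.nu)


def prob_leave_chain_pheromone(model: LeaveModel, Xi: float,
                               space_level: float) -> float:
    """Pheromone-coupled leave probability used by the default runs."""
    if Xi < 0 or space_level < 0:
        raise ValueError("Xi and space_level must be >= 0")
    b = min(model.eta * math.log(space_level + 1.0) + model.eps, 1.0)
    return model.a / (1.0 + b * Xi * Xi)


# ---------------------------------------------------------------------------
# World queries (operate on the engine's SimState, duck-typed)
# ---------------------------------------------------------------------------

def is_traversable(state: "SimState", cell: Cell) -> bool:
    """Can a walking ant step onto ``cell`` right now?

    OPEN/NEST/FOOD cells are traversable when no walker occupies them.
    DITCH cells are traversable only when bridged — a chain member occupies
    the cell — and no other walker is currently standing on the member's
    back (one bridge cell carries at most one walker at a time).
    """
    x, y = cell
    env = state.env
    if not (0 <= x < env.width and 0 <= y < env.height):
        return False
    if state.walker_occ[y, x] >= 0:
        return False
    if env.is_ditch[y, x]:
        return state.chain_occ[y, x] >= 0
    return True


def _move_candidates(state: "SimState", pos: Cell) -> list[Cell]:
    x, y = pos
    return [c for c in ((x + dx, y + dy) for dx, dy in DIRS8)
            if is_traversable(state, c)]


def _others_within(state: "SimState", ant: Ant, radius: int) -> int:
    """Number of other agents (walkers or chain members) within ``radius``."""
    x, y = ant.pos
    y0, y1 = max(0, y - radius), y + radius + 1
    x0, x1 = max(0, x - radius), x + radius + 1
    total = int(state.occ_count[y0:y1, x0:x1].sum())
    return total - 1  # the ant itself is counted exactly once


def _walkers_within(state: "SimState", ant: Ant, radius: int) -> int:
    """Number of *active* (non-Altruism) agents within ``radius`` of the ant.

    Chain members are parked infrastructure: the crowding that recruits an
    ant into a chain, and the traffic that keeps a member holding its post,
    are both made of walking nestmates.  Counting chain members here would
    let a chain recruit forever from the ants that just climbed out of it.
    """
    x, y = ant.pos
    y0, y1 = max(0, y - radius), y + radius + 1
    x0, x1 = max(0, x - radius), x + radius + 1
    count = int((state.walker_occ[y0:y1, x0:x1] >= 0).sum())
    if ant.state is not AntState.ALTRUISM:
        count -= 1  # the ant itself
    return count


def _ditch_within_1(state: "SimState", pos: Cell) -> bool:
    return bool(state.env.ditch_near[pos[1], pos[0]])


def _perceived_pheromone(state: "SimState", pos: Cell, radius: int) -> float:
    x, y = pos
    view = state.field.space[max(0, y - radius):y + radius + 1,
                             max(0, x - radius):x + radius + 1]
    return float(view.max()) if view.size else 0.0


def _move_ant(state: "SimState", ant: Ant, target: Cell) -> None:
    ox, oy = ant.pos
    state.walker_occ[oy, ox] = -1
    state.occ_count[oy, ox] -= 1
    tx, ty = target
    state.walker_occ[ty, tx] = ant.id
    state.occ_count[ty, tx] += 1
    ant.heading = (tx - ox, ty - oy)
    ant.pos = target


def _random_direction_move(state: "SimState", ant: Ant,
                           params: BehaviorParams, rng: np.random.Generator) -> bool:
    """The random-walk rule: straight ahead is free, turns cost alpha.

    Draws a direction; a direction other than the current heading is
    accepted only with probability ``alpha``; a blocked or rejected draw is
    redrawn.  An ant surrounded on all sides stays put.  Returns True if
    the ant moved.
    """
    if not _move_candidates(state, ant.pos):
        return False
    x, y = ant.pos
    for _ in range(params.max_direction_draws):
        d = DIRS8[int(rng.integers(8))]
        if d != ant.heading and rng.random() >= params.alpha:
            continue
        target = (x + d[0], y + d[1])
        if is_traversable(state, target):
            _move_ant(state, ant, target)
            return True
    return False


def pheromone_guided_move(ant: Ant, candidates: Sequence[Cell],
                          space_levels: Sequence[float],
                          rng: np.random.Generator) -> Cell:
    """Choose among free cells with probability proportional to pheromone.

    All-zero levels fall back to a uniform choice.  Only Minor ants move
    this way; Majors always use the random rule.
    """
    if not candidates:
        raise ValueError("no candidate cells")
    levels = np.asarray(space_levels, dtype=float)
    total = levels.sum()
    if total <= 0.0:
        idx = int(rng.integers(len(candidates)))
    else:
        idx = int(rng.choice(len(candidates), p=levels / total))
    return candidates[idx]


# ---------------------------------------------------------------------------
# Chain entry
# ---------------------------------------------------------------------------

def _entry_cell(state: "SimState", ant: Ant) -> Optional[Cell]:
    """Ditch cell within 1 Distance for a new chain member.

    Prefers a free ditch cell adjacent to an existing chain so the chain
    grows contiguously across the 3-cell band; otherwise any free ditch
    cell within reach.
    """
    env = state.env
    x, y = ant.pos
    free: list[Cell] = []
    adjacent_chain: list[Cell] = []
    for dx, dy in DIRS8:
        cx, cy = x + dx, y + dy
        if not (0 <= cx < env.width and 0 <= cy < env.height):
            continue
        if not env.is_ditch[cy, cx] or state.chain_occ[cy, cx] >= 0:
            continue
        if state.walker_occ[cy, cx] >= 0:
            continue
        free.append((cx, cy))
        view = state.chain_occ[max(0, cy - 1):cy + 2, max(0, cx - 1):cx + 2]
        if (view >= 0).any():
            adjacent_chain.append((cx, cy))
    pool = adjacent_chain or free
    if not pool:
        return None
    return pool[int(state.rng.integers(len(pool)))]


def _try_enter_chain(state: "SimState", ant: Ant, params: BehaviorParams) -> bool:
    if ant.caste is Caste.MAJOR and not params.majors_form_chains:
        return False
    target = _entry_cell(state, ant)
    if target is None:
        return False
    if params.use_lioni_entry:
        tx, ty = target
        view = state.chain_occ[max(0, ty - 1):ty + 2, max(0, tx - 1):tx + 2]
        xi = int((view >= 0).sum())
        if state.rng.random() >= prob_enter_chain(state.entry_model, xi):
            return False
    ox, oy = ant.pos
    state.walker_occ[oy, ox] = -1
    state.occ_count[oy, ox] -= 1
    tx, ty = target
    state.chain_occ[ty, tx] = ant.id
    state.occ_count[ty, tx] += 1
    ant.pos = target
    ant.heading = None
    state.record_transition(ant, AntState.ALTRUISM)
    ant.state = AntState.ALTRUISM
    return True


# ---------------------------------------------------------------------------
# Per-state step functions
# ---------------------------------------------------------------------------

def search_step(state: "SimState", ant: Ant, params: BehaviorParams,
                rng: np.random.Generator) -> None:
    """One Search-state action.

    In order: pick up adjacent food (-> Return); if crowded and next to a
    ditch, enter the chain (-> Altruism); otherwise move — Minors follow
    airborne pheromone when any is present among the free neighbour cells,
    and everyone else (and scent-less Minors) takes the biased random walk.
    """
    env = state.env
    x, y = ant.pos
    # 1) food within food_radius (own cell included: standing on food counts)
    r = params.food_radius
    for cy in range(max(0, y - r), min(env.height, y + r + 1)):
        for cx in range(max(0, x - r), min(env.width, x + r + 1)):
            sid = env.spot_id[cy, cx]
            if sid >= 0 and env.spots[sid].remaining_food > 0:
                spot = env.spots[sid]
                spot.remaining_food -= 1
                ant.carrying = True
                ant.cargo_from = spot.label
                state.record_transition(ant, AntState.RETURN)
                ant.state = AntState.RETURN
                return
    # 2-4) crowding / pheromone trigger and ditch -> Altruism
    if params.entry_mode == "model2":
        triggered = (_perceived_pheromone(state, ant.pos, params.pheromone_radius)
                     >= params.model2_threshold)
    else:
        triggered = _walkers_within(state, ant, params.agent_radius) > 0
    if triggered and _ditch_within_1(state, ant.pos):
        if _try_enter_chain(state, ant, params):
            return
    # 5) Minors steer by the space layer when it is non-zero nearby
    if ant.caste is Caste.MINOR:
        cands = _move_candidates(state, ant.pos)
        if cands:
            levels = [state.field.space[c[1], c[0]] for c in cands]
            if sum(levels) > 0.0:
                target = pheromone_guided_move(ant, cands, levels, rng)
                _move_ant(state, ant, target)
                return
        else:
            return  # fully surrounded: wait
    # 6) biased random walk
    _random_direction_move(state, ant, params, rng)


def _nearest_nest_cell(nest, pos: Cell) -> Cell:
    x = min(max(pos[0], nest.x_min), nest.x_max)
    y = min(max(pos[1], nest.y_min), nest.y_max)
    return (x, y)


def return_step(state: "SimState", ant: Ant, params: BehaviorParams,
                rng: np.random.Generator) -> None:
    """One Return-state action: head home and deliver.

    On a nest cell the cargo is delivered and the ant resumes searching.
    Near a ditch the ant falls back to the random walk (which is what
    carries it across bridges); otherwise it takes a free neighbouring cell
    strictly closer to the nest, ties broken uniformly, waiting if blocked.
    """
    env = state.env
    x, y = ant.pos
    if env.base_class[y, x] == CellClass.NEST:
        state.delivered[ant.cargo_from] = state.delivered.get(ant.cargo_from, 0) + 1
        ant.carrying = False
        ant.cargo_from = None
        state.record_transition(ant, AntState.SEARCH)
        ant.state = AntState.SEARCH
        return
    if _ditch_within_1(state, ant.pos):
        _random_direction_move(state, ant, params, rng)
        return
    here = chebyshev_distance(ant.pos, _nearest_nest_cell(env.nest, ant.pos))
    closer = [c for c in _move_candidates(state, ant.pos)
              if chebyshev_distance(c, _nearest_nest_cell(env.nest, c)) < here]
    if closer:
        _move_ant(state, ant, closer[int(rng.integers(len(closer)))])
    # else: blocked — wait in place


def altruism_step(state: "SimState", ant: Ant, params: BehaviorParams,
                  rng: np.random.Generator) -> None:
    """One Altruism-state action: hold the bridge or climb out.

    The ant abandons its post when the active traffic around it drops
    below ``n`` agents, or spontaneously with the pheromone-coupled
    probability Pi.  Leaving requires a free position within 1 Distance —
    open ground or the back of a neighbouring chain member (the ant climbs
    onto the bridge and walks off).  A member currently carrying a walker
    on its back is load-bearing and cannot leave; with no free position at
    all the ant is embedded in the chain and must wait.
    """
    chain = state.chains.get(ant.chain_id)
    xi = chain.size if chain is not None else 1
    space_here = float(state.field.space[ant.pos[1], ant.pos[0]])
    p1 = prob_leave_chain_pheromone(state.leave_model, xi, space_here)
    crowded = _walkers_within(state, ant, params.agent_radius) >= params.n
    if crowded and rng.random() >= p1:
        return  # stays with probability 1 - P1
    x, y = ant.pos
    if state.walker_occ[y, x] >= 0:
        return  # load-bearing: a walker is crossing on this ant's back
    exits = [c for c in ((x + dx, y + dy) for dx, dy in DIRS8)
             if is_traversable(state, c)]
    if not exits:
        return  # embedded in the chain
    target = exits[int(rng.integers(len(exits)))]
    state.chain_occ[y, x] = -1
    state.occ_count[y, x] -= 1
    tx, ty = target
    state.walker_occ[ty, tx] = ant.id
    state.occ_count[ty, tx] += 1
    ant.pos = target
    ant.heading = (tx - x, ty - y)
    ant.chain_id = None
    state.record_transition(ant, AntState.SEARCH)
    ant.state = AntState.SEARCH


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def rebuild_chains(ants: Sequence[Ant], env: GridEnvironment) -> list[Chain]:
    """Connected components (1-Distance adjacency) of Altruism-state ants.

    Each component's id is the smallest member ant id, which is stable for
    as long as that member remains in the chain.  Updates ``chain_id`` on
    the member ants.
    """
    members = [a for a in ants if a.state is AntState.ALTRUISM]
    by_cell = {a.pos: a for a in members}
    seen: set[int] = set()
    chains: list[Chain] = []
    for a in members:
        if a.id in seen:
            continue
        comp: set[int] = set()
        stack = [a]
        seen.add(a.id)
        while stack:
            cur = stack.pop()
            comp.add(cur.id)
            cx, cy = cur.pos
            for dx, dy in DIRS8:
                nb = by_cell.get((cx + dx, cy + dy))
                if nb is not None and nb.id not in seen:
                    seen.add(nb.id)
                    stack.append(nb)
        chains.append(Chain(id=min(comp), members=comp))
    chains.sort(key=lambda c: c.id)
    by_id = {a.id: a for a in members}
    for chain in chains:
        for mid in chain.members:
            by_id[mid].chain_id = chain.id
    return chains
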