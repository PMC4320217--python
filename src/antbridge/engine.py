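"""Scenario construction, the per-tick schedule, and run orchestration.

A tick proceeds in a fixed, documented order:

1. every agent acts once, in a freshly shuffled order, and depositors lay
   ground pheromone immediately after acting;
2. chains are rebuilt from the Altruism-state agents;
3. the space layer diffuses/decays, then ground evaporates into space;
4. a metrics record is appended.

Scenario presets reproduce the published experimental table: ``Env 1-x``
runs 3 Major + 100 Minor ants, ``Env 2-x`` runs 3 Major + 50 Minor, with
feeding-spot ratios A:B:C drawn from {2:1:1, 1:2:1, 1:1:2, 4:2:1}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .behavior import (Ant, AntState, BehaviorParams, Caste, Chain,
                       ChainEntryModel, ChainExitModel, LeaveModel,
                       altruism_step, rebuild_chains, return_step, search_step)
from .environment import (GridEnvironment, Rect, build_default_environment)
from .pheromone import (PheromoneField, PheromoneParams, deposit,
                        ground_space_exchange, space_diffusion_step,
                        write_snapshot)

__all__ = ["ScenarioSpec", "SimState", "PRESETS", "make_scenario",
           "step", "run", "sweep", "trial_seed"]


@dataclass
class ScenarioSpec:
    """Everything needed to build a reproducible run."""

    name: str = "custom"
    n_major: int = 3
    n_minor: int = 100
    ratio: tuple[int, int, int] = (2, 1, 1)  # food ratio A:B:C
    base_food_units: int = 100
    max_ticks: int = 10_000
    seed: int = 0
    spot_layout: Optional[dict[str, Rect]] = None
    close_top: bool = True
    width: int = 100
    height: int = 100

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0 or self.n_major + self.n_minor == 0:
            raise ValueError("need a positive number of agents")
        if any(r <= 0 for r in self.ratio):
            raise ValueError("ratio entries must be positive")


_RATIOS = {"1": (2, 1, 1), "2": (1, 2, 1), "3": (1, 1, 2), "4": (4, 2, 1)}

#: The eight published scenario presets.
PRESETS: dict[str, ScenarioSpec] = {}
for _env, _minor in (("1", 100), ("2", 50)):
    for _col, _ratio in _RATIOS.items():
        _name = f"Env {_env}-{_col}"
        PRESETS[_name] = ScenarioSpec(name=_name, n_major=3, n_minor=_minor,
                                      ratio=_ratio)


def _resolve_preset(name: str) -> ScenarioSpec:
    m = re.fullmatch(r"(?:env\s*)?([12])\s*-\s*([1-4])", name.strip().lower())
    if not m:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}")
    return PRESETS[f"Env {m.group(1)}-{m.group(2)}"]


class SimState:
    """Full mutable simulation state for one run."""

    def __init__(self, env: GridEnvironment, ants: Sequence[Ant],
                 rng: np.random.Generator,
                 pher: PheromoneParams | None = None,
                 behavior: BehaviorParams | None = None,
                 leave_model: LeaveModel | None = None,
                 entry_model: ChainEntryModel | None = None,
                 exit_model: ChainExitModel | None = None,
                 max_ticks: int = 10_000,
                 log_transitions: bool = False) -> None:
        self.env = env
        self.ants = list(ants)
        self.rng = rng
        self.pher = pher or PheromoneParams()
        self.behavior = behavior or BehaviorParams()
        self.leave_model = leave_model or LeaveModel()
        self.entry_model = entry_model or ChainEntryModel()
        self.exit_model = exit_model or ChainExitModel()
        self.max_ticks = max_ticks
        self.tick = 0
        self.field = PheromoneField(env.height, env.width)
        self.delivered: dict[str, int] = {s.label: 0 for s in env.spots}
        self.chains: dict[int, Chain] = {}
        self.chain_list: list[Chain] = []
        self.log_transitions = log_transitions
        self.transitions: list[dict] = []
        # occupancy grids: walker_occ / chain_occ hold the ant id or -1;
        # occ_count holds how many agents (walker + chain member) sit on a cell
        self.walker_occ = np.full((env.height, env.width), -1, dtype=np.int32)
        self.chain_occ = np.full((env.height, env.width), -1, dtype=np.int32)
        self.occ_count = np.zeros((env.height, env.width), dtype=np.int16)
        for ant in self.ants:
            x, y = ant.pos
            if ant.state is AntState.ALTRUISM:
                if self.chain_occ[y, x] >= 0:
                    raise ValueError(f"two chain members on cell {ant.pos}")
                self.chain_occ[y, x] = ant.id
            else:
                if self.walker_occ[y, x] >= 0:
                    raise ValueError(f"two walkers on cell {ant.pos}")
                self.walker_occ[y, x] = ant.id
            self.occ_count[y, x] += 1
        self.chain_list = rebuild_chains(self.ants, env)
        self.chains = {c.id: c for c in self.chain_list}

    # -- bookkeeping ---------------------------------------------------

    def record_transition(self, ant: Ant, to_state: AntState) -> None:
        if self.log_transitions:
            self.transitions.append({
                "tick": self.tick, "ant": ant.id,
                "from": ant.state.value, "to": to_state.value,
                "x": ant.pos[0], "y": ant.pos[1]})

    @property
    def carried_units(self) -> int:
        return sum(1 for a in self.ants if a.carrying)

    def food_audit(self) -> tuple[int, int, int, int]:
        """(delivered, remaining, carried, initial) food-unit totals."""
        delivered = sum(self.delivered.values())
        remaining = sum(s.remaining_food for s in self.env.spots)
        initial = sum(s.initial_food for s in self.env.spots)
        return delivered, remaining, self.carried_units, initial


def make_scenario(preset: str | ScenarioSpec, *,
                  seed: Optional[int] = None,
                  pher: PheromoneParams | None = None,
                  behavior: BehaviorParams | None = None,
                  leave_model: LeaveModel | None = None,
                  log_transitions: bool = False,
                  **overrides) -> SimState:
    """Build the initial :class:`SimState` for a preset name or explicit spec.

    ``overrides`` patch fields of the resolved :class:`ScenarioSpec`
    (e.g. ``base_food_units=5``); ``seed`` overrides the spec's seed.
    """
    spec = _resolve_preset(preset) if isinstance(preset, str) else preset
    if overrides:
        spec = replace(spec, **overrides)
    if seed is not None:
        spec = replace(spec, seed=seed)
    food = {label: spec.base_food_units * r
            for label, r in zip(("A", "B", "C"), spec.ratio)}
    env = build_default_environment(spec.spot_layout, food,
                                    width=spec.width, height=spec.height,
                                    close_top=spec.close_top)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    nest_cells = [(x, y)
                  for y in range(env.nest.y_min, env.nest.y_max + 1)
                  for x in range(env.nest.x_min, env.nest.x_max + 1)]
    n_ants = spec.n_major + spec.n_minor
    if n_ants > len(nest_cells):
        raise ValueError("more ants than nest cells")
    picks = rng.choice(len(nest_cells), size=n_ants, replace=False)
    ants = [Ant(id=i,
                caste=Caste.MAJOR if i < spec.n_major else Caste.MINOR,
                pos=nest_cells[int(k)])
            for i, k in enumerate(picks)]
    state = SimState(env, ants, rng, pher=pher, behavior=behavior,
                     leave_model=leave_model, max_ticks=spec.max_ticks,
                     log_transitions=log_transitions)
    state.spec = spec
    return state


_DEP_MINOR_STATES = (AntState.RETURN,)


def step(state: SimState, log: "_metrics.MetricsLog | None" = None) -> SimState:
    """Advance the simulation by one tick (see module docstring for order)."""
    ants = state.ants
    rng = state.rng
    params = state.behavior
    order = rng.permutation(len(ants))
    for idx in order:
        ant = ants[int(idx)]
        old = ant.pos
        if ant.state is AntState.SEARCH:
            search_step(state, ant, params, rng)
        elif ant.state is AntState.RETURN:
            return_step(state, ant, params, rng)
        else:
            altruism_step(state, ant, params, rng)
        deposits = (ant.caste is Caste.MAJOR
                    or (ant.caste is Caste.MINOR and ant.carrying
                        and ant.state is AntState.RETURN)
                    or (params.minor_deposit_in_search
                        and ant.caste is Caste.MINOR
                        and ant.state is AntState.SEARCH))
        if deposits:
            dx, dy = ant.pos[0] - old[0], ant.pos[1] - old[1]
            deposit(state.field, ant.pos, state.pher,
                    moved_diagonally=(dx != 0 and dy != 0))
    state.chain_list = rebuild_chains(ants, state.env)
    state.chains = {c.id: c for c in state.chain_list}
    space_diffusion_step(state.field, state.pher)
    ground_space_exchange(state.field, state.pher)
    state.tick += 1
    if log is not None:
        log.append(_metrics.snapshot(state, log.area_map))
    return state


def run(state: SimState, *, max_ticks: Optional[int] = None,
        group_interval: Optional[int] = None,
        snapshot_interval: Optional[int] = None,
        snapshot_dir: str = "snapshots",
        area_margin: int = 10) -> "_metrics.MetricsLog":
    """Run to ``max_ticks`` or until every spot is empty and all cargo home.

    ``group_interval`` additionally samples group statistics every that
    many ticks (used by :func:`sweep`); ``snapshot_interval`` dumps the
    pheromone layers as plain-text matrices at the same cadence.
    """
    if max_ticks is None:
        max_ticks = state.max_ticks
    log = _metrics.MetricsLog(area_map=_metrics.make_area_map(state.env,
                                                              margin=area_margin))
    log.meta = {"name": getattr(state, "spec", None).name
                if getattr(state, "spec", None) else "custom",
                "seed": getattr(getattr(state, "spec", None), "seed", None),
                "n_ants": len(state.ants)}
    log.append(_metrics.snapshot(state, log.area_map))
    while state.tick < max_ticks:
        step(state, log)
        delivered, remaining, carried, _ = state.food_audit()
        if (group_interval and state.tick % group_interval == 0
                and remaining > 0):
            log.group_records.append(_metrics.detect_groups(state))
        if snapshot_interval and state.tick % snapshot_interval == 0:
            write_snapshot(state.field, snapshot_dir, state.tick)
        if remaining == 0 and carried == 0:
            break
    log.events = state.transitions
    return log


def trial_seed(master_seed: int, count_index: int, trial: int) -> np.random.SeedSequence:
    """Documented counter scheme making every sweep trial re-runnable alone."""
    return np.random.SeedSequence([int(master_seed), int(count_index), int(trial)])


def sweep(agent_counts: Iterable[int], trials: int,
          base: ScenarioSpec | None = None, *,
          master_seed: int = 0,
          max_ticks: Optional[int] = None,
          group_interval: int = 25,
          min_group_size: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-formation sweep over colony sizes.

    Runs ``trials`` seeded simulations per agent count, detects groups on a
    sampled window of each run, and returns ``(per_run, aggregate)`` tables.
    The aggregate is keyed by (N_Agent, N_Group) with mean group size and
    mean count of ungrouped agents, in the shape of the published summary.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    base = base or ScenarioSpec(name="sweep", n_major=3, n_minor=30)
    rows = []
    for ci, count in enumerate(agent_counts):
        for t in range(trials):
            seed_int = int(trial_seed(master_seed, ci, t).generate_state(1)[0]
                           % (2 ** 31))
            spec = replace(base, n_minor=int(count), seed=seed_int,
                           name=f"{base.name}-n{count}-t{t}")
            state = make_scenario(spec)
            log = run(state, max_ticks=max_ticks,
                      group_interval=group_interval)
            stats = _metrics.detect_groups(log.group_records,
                                           min_size=min_group_size)
            rows.append({"N_Agent": int(count), "trial": t, "seed": seed_int,
                         "N_Group": stats.n_group,
                         "N_AgentOfGroup": stats.n_agent_of_group,
                         "N_Others": stats.n_others})
    per_run = pd.DataFrame(rows)
    aggregate = (per_run
                 .groupby(["N_Agent", "N_Group"], as_index=False)
                 .agg(N_AgentOfGroup=("N_AgentOfGroup", "mean"),
                      N_Others=("N_Others", "mean"),
                      n_trials=("trial", "size")))
    return per_run, aggregate
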