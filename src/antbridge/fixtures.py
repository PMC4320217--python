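"""Miniature deterministic worlds for fast testing and manual inspection.

These distil the essential mechanics — a nest, food, and an uncrossable
ditch — into worlds a few hundred cells in size, so behaviour can be
exercised in milliseconds instead of running the full 100x100 arena.
"""

from __future__ import annotations

import math
import numpy as np

from .behavior import Ant, AntState, BehaviorParams, Caste, LeaveModel
from .engine import SimState
from .environment import (FeedingSpot, GridEnvironment, Rect)
from .pheromone import PheromoneField

__all__ = ["corridor_world", "point_mass_field", "chain_fixture"]

_CORRIDOR_HEIGHT = 5


def corridor_world(length: int, ditch: bool = True, *,
                   n_minor: int = 5, n_major: int = 0,
                   food_units: int = 10, seed: int = 0,
                   max_ticks: int = 10_000,
                   behavior: BehaviorParams | None = None,
                   leave_model: LeaveModel | None = None) -> SimState:
    """A 5-row strip: nest at the left end, food at the right, ditch midway.

    When ``ditch`` is set, a 3-column band spanning the full strip height
    blocks the middle — impassable for a lone ant, bridgeable by a chain.
    The nest widens with the colony so every ant gets a distinct start cell.
    """
    if length < 8:
        raise ValueError("corridor length must be >= 8")
    n_ants = n_minor + n_major
    nest_cols = max(2, math.ceil(n_ants / _CORRIDOR_HEIGHT))
    nest = Rect(0, nest_cols - 1, 0, _CORRIDOR_HEIGHT - 1)
    bars: dict[str, Rect] = {}
    if ditch:
        mid = length // 2
        bars["ditch"] = Rect(mid - 1, mid + 1, 0, _CORRIDOR_HEIGHT - 1)
        if bars["ditch"].x_min <= nest.x_max + 1:
            raise ValueError("corridor too short for this colony size")
    spot = Rect(length - 2, length - 1, 0, _CORRIDOR_HEIGHT - 1)
    env = GridEnvironment(width=length, height=_CORRIDOR_HEIGHT, bars=bars,
                          nest=nest,
                          spots=[FeedingSpot("A", spot, food_units)])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nest_cells = [(x, y) for y in range(nest.y_min, nest.y_max + 1)
                  for x in range(nest.x_min, nest.x_max + 1)]
    picks = rng.choice(len(nest_cells), size=n_ants, replace=False)
    ants = [Ant(id=i,
                caste=Caste.MAJOR if i < n_major else Caste.MINOR,
                pos=nest_cells[int(k)])
            for i, k in enumerate(picks)]
    return SimState(env, ants, rng, behavior=behavior,
                    leave_model=leave_model, max_ticks=max_ticks)


def point_mass_field(shape: tuple[int, int], pos: tuple[int, int],
                     amount: float, layer: str = "ground") -> PheromoneField:
    """Field of ``shape`` (height, width) with one non-zero cell.

    ``layer`` selects where the mass sits ('ground' or 'space');
    ``pos`` is an (x, y) cell.
    """
    if layer not in ("ground", "space"):
        raise ValueError("layer must be 'ground' or 'space'")
    height, width = shape
    x, y = pos
    if not (0 <= x < width and 0 <= y < height):
        raise ValueError(f"cell {pos} outside {width}x{height} grid")
    if amount < 0:
        raise ValueError("amount must be non-negative")
    field = PheromoneField(height, width)
    getattr(field, layer)[y, x] = amount
    return field


def chain_fixture(env: GridEnvironment, ditch: Rect, k: int, *,
                  seed: int = 0) -> SimState:
    """``k`` Altruism-state agents laid contiguously across ``ditch``.

    Members start at the low wall of the crossing (short) axis and extend
    toward the far wall, so ``k`` equal to the ditch width yields a
    spanning bridge.  Raises if ``k`` exceeds the crossing width.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    horizontal = ditch.width <= ditch.height  # crossing runs along x
    capacity = ditch.width if horizontal else ditch.height
    if k > capacity:
        raise ValueError(f"k={k} exceeds ditch capacity {capacity}")
    if horizontal:
        row = (ditch.y_min + ditch.y_max) // 2
        cells = [(ditch.x_min + i, row) for i in range(k)]
    else:
        col = (ditch.x_min + ditch.x_max) // 2
        cells = [(col, ditch.y_min + i) for i in range(k)]
    ants = [Ant(id=i, caste=Caste.MINOR, pos=c, state=AntState.ALTRUISM)
            for i, c in enumerate(cells)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return SimState(env, ants, rng)
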