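"""Lattice world geometry: ditches (bars), nest, feeding spots.

The arena is a bounded 100x100 cell grid.  A rectangular enclosure built
from impassable "bars" (ditches an ant cannot cross alone) separates the
central nest from the outer foraging areas.  Distances use the Chebyshev
metric: orthogonal and diagonal neighbours are both 1 *Distance* away.

Coordinate convention (used everywhere in this package):

* cells are ``(x, y)`` integer pairs, 0-based;
* ``x`` grows rightward, ``y`` grows downward ("below" means larger y);
* numpy grids are indexed ``[y, x]``;
* published corner pairs ``(x0, y0)-(x1, y1)`` are half-open on the max
  edge, so a bar listed with corners (30, 30) and (33, 70) blocks the
  columns {30, 31, 32} — exactly 3 cells wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable

import numpy as np
from scipy.ndimage import binary_dilation

__all__ = [
    "CellClass",
    "Rect",
    "FeedingSpot",
    "GridEnvironment",
    "build_default_environment",
    "classify_cell",
    "chebyshev_distance",
    "neighborhood",
    "DEFAULT_SPOT_LAYOUT",
]

Cell = tuple[int, int]


class CellClass(IntEnum):
    """Exclusive classification of a lattice cell."""

    OPEN = 0
    DITCH = 1
    NEST = 2
    FOOD = 3


@dataclass(frozen=True)
class Rect:
    """Axis-aligned cell rectangle with inclusive bounds."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"degenerate rectangle {self}")

    @classmethod
    def from_corners(cls, x0: int, y0: int, x1: int, y1: int) -> "Rect":
        """Build from published corner coordinates, half-open on the max edge."""
        return cls(x0, x1 - 1, y0, y1 - 1)

    def contains(self, cell: Cell) -> bool:
        x, y = cell
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def cells(self) -> Iterable[Cell]:
        for y in range(self.y_min, self.y_max + 1):
            for x in range(self.x_min, self.x_max + 1):
                yield (x, y)

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def dilated(self, margin: int) -> "Rect":
        return Rect(self.x_min - margin, self.x_max + margin,
                    self.y_min - margin, self.y_max + margin)

    def clipped(self, width: int, height: int) -> "Rect":
        return Rect(max(self.x_min, 0), min(self.x_max, width - 1),
                    max(self.y_min, 0), min(self.y_max, height - 1))


@dataclass
class FeedingSpot:
    """A rectangular food patch holding an integer number of food units."""

    label: str
    rect: Rect
    initial_food: int
    remaining_food: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.initial_food < 0:
            raise ValueError("initial_food must be non-negative")
        if self.remaining_food < 0:
            self.remaining_food = self.initial_food
        if self.remaining_food > self.initial_food:
            raise ValueError("remaining_food exceeds initial_food")


class ConfigurationError(ValueError):
    """Raised when a scenario layout violates a geometric invariant."""


@dataclass
class GridEnvironment:
    """The world: grid extent, bars (ditches), nest rectangle, feeding spots.

    Construction precomputes static lookup grids used heavily by the agent
    loop: per-cell base class, per-cell spot index, and a "ditch within 1
    Distance" mask.
    """

    width: int
    height: int
    bars: dict[str, Rect]
    nest: Rect
    spots: list[FeedingSpot]

    def __post_init__(self) -> None:
        self._validate()
        self._build_grids()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        whole = Rect(0, self.width - 1, 0, self.height - 1)
        for name, bar in self.bars.items():
            if not (whole.contains((bar.x_min, bar.y_min))
                    and whole.contains((bar.x_max, bar.y_max))):
                raise ConfigurationError(f"bar {name!r} leaves the grid")
        ditch_cells = {c for bar in self.bars.values() for c in bar.cells()}
        for c in self.nest.cells():
            if c in ditch_cells:
                raise ConfigurationError("nest overlaps a ditch")
        seen: set[Cell] = set()
        for spot in self.spots:
            for c in spot.rect.cells():
                if not whole.contains(c):
                    raise ConfigurationError(
                        f"feeding spot {spot.label!r} leaves the grid")
                if c in ditch_cells:
                    raise ConfigurationError(
                        f"feeding spot {spot.label!r} overlaps a ditch")
                if self.nest.contains(c):
                    raise ConfigurationError(
                        f"feeding spot {spot.label!r} overlaps the nest")
                if c in seen:
                    raise ConfigurationError(
                        f"feeding spot {spot.label!r} overlaps another spot")
                seen.add(c)

    def _build_grids(self) -> None:
        cls = np.full((self.height, self.width), CellClass.OPEN, dtype=np.int8)
        cls[self.nest.y_min:self.nest.y_max + 1,
            self.nest.x_min:self.nest.x_max + 1] = CellClass.NEST
        for bar in self.bars.values():
            cls[bar.y_min:bar.y_max + 1, bar.x_min:bar.x_max + 1] = CellClass.DITCH
        self.base_class = cls
        spot_id = np.full((self.height, self.width), -1, dtype=np.int8)
        for i, spot in enumerate(self.spots):
            r = spot.rect
            spot_id[r.y_min:r.y_max + 1, r.x_min:r.x_max + 1] = i
        self.spot_id = spot_id
        self.is_ditch = cls == CellClass.DITCH
        # 3x3 structuring element = Chebyshev ball of radius 1
        self.ditch_near = binary_dilation(self.is_ditch, np.ones((3, 3), bool))

    # -- queries -------------------------------------------------------

    def in_bounds(self, cell: Cell) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height

    def spot_at(self, cell: Cell) -> FeedingSpot | None:
        i = self.spot_id[cell[1], cell[0]]
        return self.spots[i] if i >= 0 else None

    def spot_by_label(self, label: str) -> FeedingSpot:
        for spot in self.spots:
            if spot.label == label:
                return spot
        raise KeyError(label)


# Default feeding-spot layout: B across the left ditch, C across the right
# ditch, A below the center ditch, each an 8x8 patch centred in its outer
# strip.  The layout is only shown pictorially in the source material, so
# these are declared package defaults, overridable through the
# `environment.spots` config section.
DEFAULT_SPOT_LAYOUT: dict[str, Rect] = {
    "A": Rect(46, 53, 82, 89),
    "B": Rect(11, 18, 45, 52),
    "C": Rect(82, 89, 45, 52),
}

#: Published corner coordinates of the three ditches.
DEFAULT_BAR_CORNERS: dict[str, tuple[int, int, int, int]] = {
    "leftbar": (30, 30, 33, 70),
    "rightbar": (70, 30, 73, 70),
    "centerbar": (30, 70, 73, 73),
}

#: Fourth band closing the enclosure above the nest (see docs/methods.md):
#: without it the three bars leave the nest open toward the top of the grid
#: and the world would not split into an inner and an outer part.
TOPBAR_CORNERS: tuple[int, int, int, int] = (30, 27, 73, 30)


def build_default_environment(
    spot_layout: dict[str, Rect] | None = None,
    food_units: dict[str, int] | None = None,
    *,
    width: int = 100,
    height: int = 100,
    close_top: bool = True,
) -> GridEnvironment:
    """Construct the standard 100x100 arena.

    Parameters
    ----------
    spot_layout
        Mapping spot label -> rectangle.  Defaults to
        :data:`DEFAULT_SPOT_LAYOUT`.
    food_units
        Mapping spot label -> initial food units (default 100 each).
    close_top
        Add the fourth ditch band sealing the nest from above so the bars
        divide the space into exactly two parts.
    """
    if spot_layout is None:
        spot_layout = DEFAULT_SPOT_LAYOUT
    if food_units is None:
        food_units = {label: 100 for label in spot_layout}
    bars = {name: Rect.from_corners(*c) for name, c in DEFAULT_BAR_CORNERS.items()}
    if close_top:
        bars["topbar"] = Rect.from_corners(*TOPBAR_CORNERS)
    left, right = bars["leftbar"], bars["rightbar"]
    nest = Rect(left.x_max + 1, right.x_min - 1, left.y_min, left.y_max)
    spots = [
        FeedingSpot(label, rect, int(food_units.get(label, 0)))
        for label, rect in sorted(spot_layout.items())
    ]
    return GridEnvironment(width=width, height=height, bars=bars,
                           nest=nest, spots=spots)


def classify_cell(env: GridEnvironment, pos: Cell) -> CellClass:
    """Classify a cell as OPEN, DITCH, NEST or FOOD.

    FOOD is dynamic: a spot cell counts as FOOD only while the spot still
    holds food; an exhausted spot reverts to OPEN ground.
    """
    if not env.in_bounds(pos):
        raise IndexError(f"cell {pos} outside {env.width}x{env.height} grid")
    base = CellClass(env.base_class[pos[1], pos[0]])
    if base == CellClass.OPEN:
        spot = env.spot_at(pos)
        if spot is not None and spot.remaining_food > 0:
            return CellClass.FOOD
    return base


def chebyshev_distance(p: Cell, q: Cell) -> int:
    """Lattice distance where diagonal neighbours count as 1 Distance."""
    return max(abs(p[0] - q[0]), abs(p[1] - q[1]))


def neighborhood(env: GridEnvironment, pos: Cell, radius: int = 1) -> list[Cell]:
    """All in-bounds cells within ``radius`` Distances of ``pos``, excluding it."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    x, y = pos
    out: list[Cell] = []
    for ny in range(max(0, y - radius), min(env.height, y + radius + 1)):
        for nx in range(max(0, x - radius), min(env.width, x + radius + 1)):
            if (nx, ny) != pos:
                out.append((nx, ny))
    return out
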