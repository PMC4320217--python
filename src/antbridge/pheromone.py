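"""Two-layer pheromone field: ground deposits and an airborne space layer.

Ants deposit pheromone on the *ground*; it evaporates at rate ``r_e`` into
the *space* layer above, which is the only layer ants perceive.  Each tick
the space layer undergoes a decay-plus-diffusion update

    space'(x,y) = r_A * s + r_B * (sum of 4 orthogonal neighbours - 4 s)
                        + r_C * (sum of 4 diagonal neighbours - 4 s)

followed by the evaporation exchange

    space(t+1)  = space'(t) + r_e * ground(t)
    ground(t+1) = ground(t) - r_e * ground(t)

Out-of-grid neighbours contribute 0 (absorbing boundary) and any negative
result is clipped to 0 (counted in ``PheromoneField.clip_events``).

The default rates r_A : r_B : r_C = 0.788 : 0.043 : 0.010 sum, with the
eight neighbour weights, to exactly 1; the alternative exactly-conservative
"redistribute" kernel is available as ``kernel='conservative'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PheromoneParams",
    "PheromoneField",
    "space_diffusion_step",
    "ground_space_exchange",
    "deposit",
    "total_pheromone",
]


@dataclass
class PheromoneParams:
    """Rates of the pheromone update and deposit magnitudes.

    r_A : decay ratio of the space layer (dimensionless, default 0.788)
    r_B : diffusion rate to the 4 orthogonal neighbours (default 0.043)
    r_C : diffusion rate to the 4 diagonal neighbours (default 0.010)
    r_e : ground-to-space evaporation rate per tick (default 0.05)
    deposit_ground : units laid on the ground per depositing agent per tick
    diagonal_deposit_factor : deposit multiplier after a diagonal move —
        diagonally laid pheromone is diminished relative to orthogonal moves
    kernel : 'laplacian' (literal decay+Laplacian form above) or
        'conservative' (space' = r_A*s + r_B*sum_orth + r_C*sum_diag)
    """

    r_A: float = 0.788
    r_B: float = 0.043
    r_C: float = 0.010
    r_e: float = 0.05
    deposit_ground: float = 1.0
    diagonal_deposit_factor: float = 0.5
    kernel: str = "laplacian"

    def __post_init__(self) -> None:
        for name in ("r_A", "r_B", "r_C", "r_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.diagonal_deposit_factor <= 1.0:
            raise ValueError("diagonal_deposit_factor must be in (0, 1]")
        if self.kernel not in ("laplacian", "conservative"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


class PheromoneField:
    """Paired ``ground`` and ``space`` concentration grids (indexed [y, x])."""

    __slots__ = ("space", "ground", "clip_events")

    def __init__(self, height: int, width: int) -> None:
        self.space = np.zeros((height, width), dtype=np.float64)
        self.ground = np.zeros((height, width), dtype=np.float64)
        self.clip_events = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.space.shape

    def copy(self) -> "PheromoneField":
        out = PheromoneField(*self.shape)
        out.space = self.space.copy()
        out.ground = self.ground.copy()
        out.clip_events = self.clip_events
        return out


def _shift_sums(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sums over the 4 orthogonal and 4 diagonal neighbours, zeros past edges."""
    orth = np.zeros_like(s)
    orth[1:, :] += s[:-1, :]
    orth[:-1, :] += s[1:, :]
    orth[:, 1:] += s[:, :-1]
    orth[:, :-1] += s[:, 1:]
    diag = np.zeros_like(s)
    diag[1:, 1:] += s[:-1, :-1]
    diag[1:, :-1] += s[:-1, 1:]
    diag[:-1, 1:] += s[1:, :-1]
    diag[:-1, :-1] += s[1:, 1:]
    return orth, diag


def space_diffusion_step(field: PheromoneField, params: PheromoneParams) -> np.ndarray:
    """Apply one synchronous decay-diffusion update to the space layer.

    Returns the updated space grid (also stored back on ``field``).
    """
    s = field.space
    if s.min() < 0:
        raise ValueError("space layer holds negative pheromone")
    orth, diag = _shift_sums(s)
    if params.kernel == "laplacian":
        new = (params.r_A * s
               + params.r_B * (orth - 4.0 * s)
               + params.r_C * (diag - 4.0 * s))
    else:
        new = params.r_A * s + params.r_B * orth + params.r_C * diag
    neg = new < 0.0
    if neg.any():
        field.clip_events += int(neg.sum())
        new[neg] = 0.0
    field.space = new
    return new


def ground_space_exchange(field: PheromoneField, params: PheromoneParams) -> PheromoneField:
    """Move fraction ``r_e`` of every ground cell up into the space layer."""
    moved = params.r_e * field.ground
    field.space += moved
    field.ground -= moved
    return field


def deposit(field: PheromoneField, pos: tuple[int, int],
            params: PheromoneParams, moved_diagonally: bool = False) -> np.ndarray:
    """Lay one agent's deposit on the ground at ``pos``.

    A diagonal move lays ``deposit_ground * diagonal_deposit_factor``;
    an orthogonal move (or standing still) lays the full amount.
    """
    x, y = pos
    amount = params.deposit_ground
    if moved_diagonally:
        amount *= params.diagonal_deposit_factor
    field.ground[y, x] += amount
    return field.ground


def total_pheromone(field: PheromoneField) -> tuple[float, float]:
    """Return ``(space total, ground total)``."""
    return float(field.space.sum()), float(field.ground.sum())


def write_snapshot(field: PheromoneField, out_dir: str, tick: int) -> list[str]:
    """Dump both layers as plain-text matrices (one file per layer).

    Debug aid: files ``space_<tick>.txt`` / ``ground_<tick>.txt`` hold one
    row per grid row, ``%.6g`` formatted, loadable with ``numpy.loadtxt``.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for layer in ("space", "ground"):
        path = os.path.join(out_dir, f"{layer}_{tick:06d}.txt")
        np.savetxt(path, getattr(field, layer), fmt="%.6g")
        paths.append(path)
    return paths
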