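"""Observation of runs: occupancy, bridges, depletion order, group statistics.

The per-tick record mirrors what the published experiments plot: how many
agents occupy each foraging area (A/B/C), how much food each spot still
holds, the sizes of all living chains, and whether each ditch currently
carries a spanning bridge.  Group statistics summarise how a colony
partitions into concurrent search parties.
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import TYPE_CHECKING, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .behavior import AntState
from .environment import GridEnvironment, Rect, chebyshev_distance

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimState

__all__ = ["MetricsRecord", "MetricsLog", "GroupStats", "make_area_map",
           "snapshot", "agents_by_area", "bridge_active", "detect_groups",
           "depletion_order", "write_outputs"]


@dataclass
class MetricsRecord:
    tick: int
    agents_in_area: dict[str, int]
    remaining_food: dict[str, int]
    delivered: dict[str, int]
    chain_sizes: list[int]
    bridges_active: dict[str, bool]
    carried: int


@dataclass
class GroupStats:
    """Colony partition summary: groups are clusters of >= min_size agents."""

    n_agent: int
    n_group: int
    n_agent_of_group: Optional[float]  # mean group size; None when no group
    n_others: int


@dataclass
class MetricsLog:
    """Per-tick records plus sampled group statistics and event stream."""

    area_map: dict[str, Rect]
    records: list[MetricsRecord] = dc_field(default_factory=list)
    group_records: list[GroupStats] = dc_field(default_factory=list)
    events: list[dict] = dc_field(default_factory=list)
    meta: dict = dc_field(default_factory=dict)

    def append(self, record: MetricsRecord) -> None:
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {"tick": r.tick, "carried": r.carried,
                         "n_chains": len(r.chain_sizes),
                         "max_chain": max(r.chain_sizes, default=0),
                         "in_chains": sum(r.chain_sizes),
                         "chain_sizes": ";".join(map(str, r.chain_sizes))}
            for k, v in r.agents_in_area.items():
                row[f"area_{k}"] = v
            for k, v in r.remaining_food.items():
                row[f"food_{k}"] = v
            for k, v in r.delivered.items():
                row[f"delivered_{k}"] = v
            for k, v in r.bridges_active.items():
                row[f"bridge_{k}"] = v
            rows.append(row)
        if not rows:  # header-only frame
            return pd.DataFrame(columns=["tick", "carried", "n_chains",
                                         "max_chain", "in_chains", "chain_sizes"])
        return pd.DataFrame(rows)


def make_area_map(env: GridEnvironment, margin: int = 10) -> dict[str, Rect]:
    """Occupancy areas: each spot rectangle dilated by ``margin`` cells.

    The published curves count "agents in each area" without printing area
    extents; with the default layout and margin each area covers the middle
    band of its outer strip (left, right, bottom), so the counts track the
    regional search parties rather than only the ants standing on food.
    """
    return {spot.label: spot.rect.dilated(margin).clipped(env.width, env.height)
            for spot in env.spots}


def agents_by_area(state: "SimState", area_map: dict[str, Rect]) -> dict[str, int]:
    """Count agents per labelled area; nest dwellers and the rest separately."""
    counts = {label: 0 for label in area_map}
    counts["nest"] = 0
    counts["other"] = 0
    nest = state.env.nest
    for ant in state.ants:
        if nest.contains(ant.pos):
            counts["nest"] += 1
            continue
        for label, rect in area_map.items():
            if rect.contains(ant.pos):
                counts[label] += 1
                break
        else:
            counts["other"] += 1
    return counts


def _chain_components(cells: Sequence[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    cellset = set(cells)
    comps = []
    seen: set[tuple[int, int]] = set()
    for c in cells:
        if c in seen:
            continue
        comp = []
        stack = [c]
        seen.add(c)
        while stack:
            x, y = stack.pop()
            comp.append((x, y))
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nb = (x + dx, y + dy)
                    if nb in cellset and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        comps.append(comp)
    return comps


def bridge_active(state: "SimState", ditch: Rect) -> bool:
    """Is there a chain spanning this ditch from one side to the other?

    True iff some connected set of Altruism-state agents occupies ditch
    cells forming a 1-Distance path whose ends touch traversable ground on
    the two opposite sides of the band (crossing its short dimension).
    """
    env = state.env
    members = [a.pos for a in state.ants
               if a.state is AntState.ALTRUISM and ditch.contains(a.pos)]
    if not members:
        return False
    horizontal_crossing = ditch.width <= ditch.height  # cross the short axis
    for comp in _chain_components(members):
        if horizontal_crossing:
            lo = any(x == ditch.x_min and _open_beyond(env, x - 1, y)
                     for x, y in comp)
            hi = any(x == ditch.x_max and _open_beyond(env, x + 1, y)
                     for x, y in comp)
        else:
            lo = any(y == ditch.y_min and _open_beyond(env, x, y - 1)
                     for x, y in comp)
            hi = any(y == ditch.y_max and _open_beyond(env, x, y + 1)
                     for x, y in comp)
        if lo and hi:
            return True
    return False


def _open_beyond(env: GridEnvironment, x: int, y: int) -> bool:
    return (0 <= x < env.width and 0 <= y < env.height
            and not env.is_ditch[y, x])


def detect_groups(source: Union["SimState", Sequence[GroupStats]],
                  radius: int = 2, min_size: int = 10) -> GroupStats:
    """Cluster non-nest agents into groups and summarise the partition.

    On a single state: clusters are connected components of agents outside
    the nest under <= ``radius`` Distance adjacency; clusters of at least
    ``min_size`` members count as groups.  On a window (a sequence of
    per-tick :class:`GroupStats`): reports the modal per-tick group count
    and the mean statistics over the ticks attaining it.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not hasattr(source, "ants"):
        return _windowed_groups(list(source))
    state = source
    nest = state.env.nest
    outside = [a.pos for a in state.ants if not nest.contains(a.pos)]
    n_agent = len(state.ants)
    if not outside:
        return GroupStats(n_agent, 0, None, 0)
    # union-find over pairwise Chebyshev adjacency (colony sizes are small)
    parent = list(range(len(outside)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(outside)):
        for j in range(i + 1, len(outside)):
            if chebyshev_distance(outside[i], outside[j]) <= radius:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    sizes = Counter(find(i) for i in range(len(outside)))
    groups = [s for s in sizes.values() if s >= min_size]
    n_others = sum(s for s in sizes.values() if s < min_size)
    mean_size = float(np.mean(groups)) if groups else None
    return GroupStats(n_agent, len(groups), mean_size, n_others)


def _windowed_groups(records: list[GroupStats]) -> GroupStats:
    if not records:
        return GroupStats(0, 0, None, 0)
    modal_n, _ = Counter(r.n_group for r in records).most_common(1)[0]
    hits = [r for r in records if r.n_group == modal_n]
    sizes = [r.n_agent_of_group for r in hits if r.n_agent_of_group is not None]
    return GroupStats(
        n_agent=hits[-1].n_agent,
        n_group=modal_n,
        n_agent_of_group=float(np.mean(sizes)) if sizes else None,
        n_others=int(round(np.mean([r.n_others for r in hits]))))


_NEVER = None  # sentinel for spots never exhausted


def depletion_order(log: MetricsLog) -> list[tuple[str, Optional[int]]]:
    """Spot labels ordered by the tick their food first reached zero.

    Spots never exhausted come last with a ``None`` tick; ties break by
    label order.
    """
    first_zero: dict[str, Optional[int]] = {}
    for r in log.records:
        for label, remaining in r.remaining_food.items():
            if label not in first_zero and remaining == 0:
                first_zero[label] = r.tick
    labels = sorted({label for r in log.records[:1]
                     for label in r.remaining_food})
    order = sorted(labels,
                   key=lambda lb: (first_zero.get(lb) is None,
                                   first_zero.get(lb, 0), lb))
    return [(lb, first_zero.get(lb, _NEVER)) for lb in order]


def snapshot(state: "SimState", area_map: dict[str, Rect]) -> MetricsRecord:
    """Build the per-tick metrics record for the current state."""
    return MetricsRecord(
        tick=state.tick,
        agents_in_area=agents_by_area(state, area_map),
        remaining_food={s.label: s.remaining_food for s in state.env.spots},
        delivered=dict(state.delivered),
        chain_sizes=sorted((c.size for c in state.chain_list), reverse=True),
        bridges_active={name: bridge_active(state, rect)
                        for name, rect in state.env.bars.items()},
        carried=state.carried_units)


def write_outputs(log: MetricsLog, stats: Optional[GroupStats],
                  out_dir: str) -> dict[str, str]:
    """Write metrics.csv (per tick), events.ndjson and summary.json.

    Returns the mapping of artefact name to file path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {"metrics": os.path.join(out_dir, "metrics.csv"),
             "events": os.path.join(out_dir, "events.ndjson"),
             "summary": os.path.join(out_dir, "summary.json")}
    log.to_dataframe().to_csv(paths["metrics"], index=False)
    with open(paths["events"], "w") as fh:
        for ev in log.events:
            fh.write(json.dumps(ev) + "\n")
    last = log.records[-1] if log.records else None
    summary = {
        "meta": log.meta,
        "ticks": last.tick if last else 0,
        "delivered": dict(last.delivered) if last else {},
        "remaining_food": dict(last.remaining_food) if last else {},
        "depletion_order": [[lb, tk] for lb, tk in depletion_order(log)],
        "group_stats": None if stats is None else {
            "N_Agent": stats.n_agent, "N_Group": stats.n_group,
            "N_AgentOfGroup": stats.n_agent_of_group,
            "N_Others": stats.n_others},
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths
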