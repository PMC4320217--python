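"""YAML configuration: one structured file describing a full run.

Sections: ``scenario`` (preset/counts/ratio/food/seed), ``environment``
(grid size, optional spot rectangles, enclosure closing), ``pheromone``
(rates and deposits), ``behavior`` (radii, thresholds, movement),
``leave_model`` (the pheromone-coupled leave probability) and ``output``
(metrics/snapshot intervals).  Every key has a default, so a config file
only needs what it overrides.
"""

from __future__ import annotations

import dataclasses
from typing import Any, TextIO, Union

import yaml

from .behavior import BehaviorParams, LeaveModel
from .engine import ScenarioSpec, SimState, _resolve_preset, make_scenario
from .environment import Rect
from .pheromone import PheromoneParams

__all__ = ["default_config", "load_config", "dump_config", "state_from_config"]


def _asdict_flat(obj) -> dict[str, Any]:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def default_config(preset: str | None = None) -> dict[str, Any]:
    """Full config dict with package defaults, optionally from a preset."""
    spec = _resolve_preset(preset) if preset else ScenarioSpec()
    scenario = _asdict_flat(spec)
    scenario["ratio"] = list(spec.ratio)
    spots = scenario.pop("spot_layout")
    close_top = scenario.pop("close_top")
    width = scenario.pop("width")
    height = scenario.pop("height")
    return {
        "scenario": scenario,
        "environment": {
            "width": width, "height": height, "close_top": close_top,
            "spots": None if spots is None else {
                label: [r.x_min, r.x_max, r.y_min, r.y_max]
                for label, r in spots.items()},
        },
        "pheromone": _asdict_flat(PheromoneParams()),
        "behavior": _asdict_flat(BehaviorParams()),
        "leave_model": _asdict_flat(LeaveModel()),
        "output": {"metrics_interval": 1, "snapshot_interval": None,
                   "group_interval": None, "dir": "out"},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: Union[str, TextIO]) -> dict[str, Any]:
    """Read a YAML config and merge it over the defaults."""
    if hasattr(source, "read"):
        user = yaml.safe_load(source) or {}
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    preset = user.get("scenario", {}).get("name")
    try:
        base = default_config(preset)
    except KeyError:
        base = default_config()
    return _merge(base, user)


def dump_config(cfg: dict[str, Any], target: Union[str, TextIO, None] = None) -> str:
    text = yaml.safe_dump(cfg, sort_keys=False)
    if target is None:
        return text
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)
    return text


def state_from_config(cfg: dict[str, Any], *, seed: int | None = None,
                      log_transitions: bool = False) -> SimState:
    """Materialise the initial :class:`SimState` a config describes."""
    sc = dict(cfg.get("scenario", {}))
    envc = cfg.get("environment", {})
    spots = envc.get("spots")
    spec = ScenarioSpec(
        name=sc.get("name", "custom"),
        n_major=int(sc.get("n_major", 3)),
        n_minor=int(sc.get("n_minor", 100)),
        ratio=tuple(sc.get("ratio", (2, 1, 1))),
        base_food_units=int(sc.get("base_food_units", 100)),
        max_ticks=int(sc.get("max_ticks", 10_000)),
        seed=int(sc.get("seed", 0)),
        spot_layout=None if spots is None else {
            label: Rect(*map(int, r)) for label, r in spots.items()},
        close_top=bool(envc.get("close_top", True)),
        width=int(envc.get("width", 100)),
        height=int(envc.get("height", 100)),
    )
    return make_scenario(
        spec, seed=seed,
        pher=PheromoneParams(**cfg.get("pheromone", {})),
        behavior=BehaviorParams(**cfg.get("behavior", {})),
        leave_model=LeaveModel(**cfg.get("leave_model", {})),
        log_transitions=log_transitions)
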