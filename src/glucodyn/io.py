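"""Serialization of parameter sets and time courses.

Parameter sets go to flat key-value JSON/YAML with units recorded; time
courses go to tidy CSV with columns ``well_id, time_days, live_pct,
dead_pct``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .model import BystanderRelation, GlobalParams, InhibitionParams, TimeCourse

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "write_params",
    "read_params",
    "write_timecourses",
    "read_timecourses",
]

_UNITS = {
    "k_p": "1/day",
    "k_d": "1/day",
    "v": "mM/(cell day)",
    "theta": "cells",
    "G_star": "mM",
    "G_min": "mM",
    "k_bys_0": "1/day",
    "alpha": "1/mM",
    "beta": "1/day",
    "g_in": "1/cell (per dose in uM)",
}


def params_to_dict(obj) -> dict:
    """Flatten a parameter object to a tagged, unit-annotated mapping."""
    if isinstance(obj, GlobalParams):
        values = {k: getattr(obj, k) for k in ("k_p", "k_d", "v", "theta", "G_star", "G_min")}
        kind = "global_params"
    elif isinstance(obj, BystanderRelation):
        values = {k: getattr(obj, k) for k in ("k_bys_0", "alpha", "beta")}
        kind = "bystander_relation"
    elif isinstance(obj, InhibitionParams):
        values = {"g_in": {str(d): g for d, g in obj.g_in.items()}}
        kind = "inhibition_params"
    else:
        raise TypeError(f"unsupported parameter object {type(obj).__name__}")
    return {
        "kind": kind,
        "values": values,
        "units": {k: _UNITS[k] for k in values},
    }


def params_from_dict(payload: Mapping):
    kind = payload.get("kind")
    values = payload.get("values", {})
    if kind == "global_params":
        return GlobalParams(**values)
    if kind == "bystander_relation":
        return BystanderRelation(**values)
    if kind == "inhibition_params":
        return InhibitionParams({float(d): float(g) for d, g in values["g_in"].items()})
    raise ValueError(f"unknown parameter payload kind {kind!r}")


def write_params(path, *objects) -> None:
    """Write one or more parameter objects to a JSON or YAML file."""
    path = Path(path)
    payload = [params_to_dict(o) for o in objects]
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_params(path) -> list:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return [params_from_dict(p) for p in payload]


def write_timecourses(path, courses: Mapping[str, TimeCourse]) -> None:
    rows = []
    for well_id, tc in courses.items():
        for t, live, dead in zip(tc.times, tc.live, tc.dead):
            rows.append((well_id, t, live, dead))
    df = pd.DataFrame(rows, columns=["well_id", "time_days", "live_pct", "dead_pct"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_timecourses(path) -> dict[str, TimeCourse]:
    df = pd.read_csv(path)
    required = ["well_id", "time_days", "live_pct", "dead_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"time-course file {path} is missing column(s): {', '.join(missing)}")
    out = {}
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_days")
        out[str(well_id)] = TimeCourse(
            times=grp["time_days"].to_numpy(),
            live=grp["live_pct"].to_numpy(),
            dead=grp["dead_pct"].to_numpy(),
        )
    return out
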