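"""Strict CSV readers/writers for the shared table dialects.

All tables are UTF-8, comma-separated with a header row.  The events
dialect is ``fly_id,treatment,time_s,direction[,arm_from,arm_to]`` with
direction codes exactly 'L'/'R'; anything else (e.g. "left") is a parse
error, never a silent coercion.  Trajectories are
``fly_id,time_s,x_mm,y_mm``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scoring import MazeGeometry

log = logging.getLogger("turnvar")

__all__ = [
    "read_events",
    "write_events",
    "read_trajectories",
    "read_geometry",
    "write_geometry",
]

_EVENT_COLS = ["fly_id", "treatment", "time_s", "direction"]
_OPT_EVENT_COLS = ["arm_from", "arm_to"]
_TRAJ_COLS = ["fly_id", "time_s", "x_mm", "y_mm"]


def read_events(path) -> pd.DataFrame:
    """Read a turn-event table, validating the dialect strictly."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        log.warning("%s: events file is empty (header only)", path)
        return df
    df["time_s"] = df["time_s"].astype(float)
    bad = sorted(set(df["direction"].astype(str).unique()) - {"L", "R"})
    if bad:
        raise ValueError(f"{path}: direction values outside {{L, R}}: {bad}")
    for c in _OPT_EVENT_COLS:
        if c in df.columns:
            df[c] = df[c].astype(np.int64)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    """Write an events table losslessly (read_events round-trips it)."""
    cols = _EVENT_COLS + [c for c in _OPT_EVENT_COLS if c in events.columns]
    events[cols].to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    """Read centroid trajectories (fly_id, time_s, x_mm, y_mm)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in ("time_s", "x_mm", "y_mm"):
        df[c] = df[c].astype(float)
    if len(df) and not np.all(np.isfinite(df[["time_s", "x_mm", "y_mm"]].to_numpy())):
        raise ValueError(f"{path}: non-finite coordinates or times present")
    return df


def read_geometry(path) -> MazeGeometry:
    """Load a MazeGeometry from YAML; fields mirror the dataclass."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "center_xy" in raw:
        raw["center_xy"] = tuple(float(v) for v in raw["center_xy"])
    if "arm_angles_deg" in raw:
        raw["arm_angles_deg"] = tuple(float(v) for v in raw["arm_angles_deg"])
    return MazeGeometry(**raw)


def write_geometry(geometry: MazeGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "center_xy": list(geometry.center_xy),
                "arm_angles_deg": list(geometry.arm_angles_deg),
                "arm_length_mm": geometry.arm_length_mm,
                "center_radius_mm": geometry.center_radius_mm,
                "commit_radius_mm": geometry.commit_radius_mm,
                "extent_tol_mm": geometry.extent_tol_mm,
            },
            fh,
        )
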