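"""Scoring of Y-maze centroid trajectories into left/right turn events.

A fly in a symmetric three-armed maze makes a decision each time it leaves
one arm and commits to another.  This module converts a time-sorted centroid
track (x, y in mm) into a sequence of timestamped turn events with a
left/right label.

Commitment is defined with hysteresis: a fly counts as "in" an arm only once
its centroid is at least ``commit_radius_mm`` from the maze center, while the
central decision zone extends only to ``center_radius_mm``.  The gap between
the two radii absorbs tracking jitter so that boundary chatter never emits
spurious events.

The left/right labelling needs a geometric convention, because "right" in a
three-armed maze is ambiguous until an arm indexing orientation is fixed.
With arms indexed clockwise (viewed from above), moving to the clockwise
neighbour ``(i + 1) mod 3`` is a right turn under the default ``cw-right``
convention; ``ccw-right`` flips every label.  All dispersion statistics
computed downstream are invariant to this choice when there is no mean
directional bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MazeGeometry",
    "Zone",
    "assign_zone",
    "assign_zones",
    "score_turns",
    "turn_direction",
    "CONVENTIONS",
]

#: Integer zone codes used internally; arms are their own index 0..2.
_CENTER = -1
_OUT = -2

#: Public zone names in the order tests and QC tables use them.
Zone = ("CENTER", "ARM0", "ARM1", "ARM2", "OUT")

CONVENTIONS = ("cw-right", "ccw-right")


@dataclass(frozen=True)
class MazeGeometry:
    """Geometry of one symmetric three-armed (Y) maze, lengths in mm.

    Parameters
    ----------
    center_xy
        Maze center in the track's coordinate frame.
    arm_angles_deg
        Bearings of the three arm axes, degrees, pairwise distinct mod 360.
    arm_length_mm
        Length of each arm from the center (default 12 mm).
    center_radius_mm
        Radius of the central decision zone.
    commit_radius_mm
        Radial distance at which a fly counts as committed to an arm;
        must exceed ``center_radius_mm`` (hysteresis band).
    extent_tol_mm
        Tolerance beyond ``arm_length_mm`` before a point is flagged OUT.
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    arm_angles_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)
    arm_length_mm: float = 12.0
    center_radius_mm: float = 2.0
    commit_radius_mm: float = 4.0
    extent_tol_mm: float = 0.5

    def __post_init__(self) -> None:
        if len(self.arm_angles_deg) != 3:
            raise ValueError("arm_angles_deg: exactly three arm bearings required")
        ang = np.asarray(self.arm_angles_deg, dtype=float) % 360.0
        if len(np.unique(np.round(ang, 9))) != 3:
            raise ValueError("arm_angles_deg: bearings must be pairwise distinct modulo 360")
        if not (0.0 < self.center_radius_mm < self.commit_radius_mm <= self.arm_length_mm):
            raise ValueError(
                "radii: require 0 < center_radius_mm < commit_radius_mm <= arm_length_mm, "
                f"got center={self.center_radius_mm}, commit={self.commit_radius_mm}, "
                f"arm_length={self.arm_length_mm}"
            )
        if self.extent_tol_mm < 0:
            raise ValueError("extent_tol_mm: must be nonnegative")


def turn_direction(arm_from: int, arm_to: int, convention: str = "cw-right") -> str:
    """Left/right label of an arm-to-arm transition.

    Arms are indexed clockwise viewed from above.  Under ``cw-right`` the
    clockwise neighbour ``(arm_from + 1) mod 3`` is a right turn and the
    counterclockwise neighbour a left turn; ``ccw-right`` swaps the labels.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention: must be one of {CONVENTIONS}, got {convention!r}")
    if arm_from not in (0, 1, 2) or arm_to not in (0, 1, 2):
        raise ValueError(f"arm indices must be in 0..2, got ({arm_from}, {arm_to})")
    if arm_from == arm_to:
        raise ValueError(f"arm_from and arm_to must differ, both are {arm_from}")
    cw = (arm_from + 1) % 3 == arm_to
    if convention == "cw-right":
        return "R" if cw else "L"
    return "L" if cw else "R"


def _zone_codes(xy: np.ndarray, geometry: MazeGeometry) -> np.ndarray:
    """Vectorized zone assignment; returns int codes (-2 OUT, -1 CENTER, 0..2 arms)."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim == 1:
        xy = xy[None, :]
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    dx = xy[:, 0] - geometry.center_xy[0]
    dy = xy[:, 1] - geometry.center_xy[1]
    dist = np.hypot(dx, dy)
    bearing = np.degrees(np.arctan2(dy, dx)) % 360.0

    # angular distance to each arm axis; ties break to the lowest arm index
    # because argmin returns the first minimum
    arm_ang = np.asarray(geometry.arm_angles_deg, dtype=float) % 360.0
    diff = np.abs(bearing[:, None] - arm_ang[None, :])
    diff = np.minimum(diff, 360.0 - diff)
    nearest = np.argmin(diff, axis=1)

    codes = nearest.astype(np.int64)
    codes[dist < geometry.center_radius_mm] = _CENTER
    codes[dist > geometry.arm_length_mm + geometry.extent_tol_mm] = _OUT
    return codes


def assign_zones(xy: np.ndarray, geometry: MazeGeometry) -> np.ndarray:
    """Zone name for each row of an (n, 2) coordinate array."""
    codes = _zone_codes(xy, geometry)
    names = np.empty(codes.shape, dtype=object)
    names[codes == _CENTER] = "CENTER"
    names[codes == _OUT] = "OUT"
    for k in range(3):
        names[codes == k] = f"ARM{k}"
    return names


def assign_zone(point: Iterable[float], geometry: MazeGeometry) -> str:
    """Zone of a single (x, y) point in mm."""
    x, y = point
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("coordinates must be finite")
    return assign_zones(np.array([[x, y]]), geometry)[0]


def score_turns(
    track: pd.DataFrame,
    geometry: MazeGeometry | None = None,
    convention: str = "cw-right",
    out_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Score a single fly's centroid track into turn events.

    Parameters
    ----------
    track
        Time-sorted DataFrame with columns ``time_s``, ``x_mm``, ``y_mm``.
    geometry
        Maze geometry; defaults to the standard 12 mm symmetric maze.
    convention
        Direction convention, ``cw-right`` (default) or ``ccw-right``.
    out_threshold
        Fraction of OUT samples above which the track is QC-flagged.

    Returns
    -------
    events, qc
        ``events`` has columns ``time_s``, ``direction``, ``arm_from``,
        ``arm_to``; a turn is emitted when the fly, having been committed to
        one arm, next becomes committed to a different arm, timestamped at
        the first committed sample in the new arm.  ``qc`` reports
        ``n_samples``, ``out_fraction``, ``n_turns`` and an ``ok`` flag.
    """
    if geometry is None:
        geometry = MazeGeometry()
    for col in ("time_s", "x_mm", "y_mm"):
        if col not in track.columns:
            raise ValueError(f"track: missing required column {col!r}")
    t = track["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("track: time_s must be sorted ascending")

    empty = pd.DataFrame(
        {"time_s": pd.Series(dtype=float), "direction": pd.Series(dtype=object),
         "arm_from": pd.Series(dtype=np.int64), "arm_to": pd.Series(dtype=np.int64)}
    )
    if len(track) < 2:
        qc = {"n_samples": len(track), "out_fraction": 0.0, "n_turns": 0, "ok": True}
        return empty, qc

    xy = track[["x_mm", "y_mm"]].to_numpy(dtype=float)
    codes = _zone_codes(xy, geometry)
    dist = np.hypot(xy[:, 0] - geometry.center_xy[0], xy[:, 1] - geometry.center_xy[1])
    out_fraction = float(np.mean(codes == _OUT))

    committed = (codes >= 0) & (dist >= geometry.commit_radius_mm)
    idx = np.flatnonzero(committed)
    if idx.size == 0:
        qc = {"n_samples": len(track), "out_fraction": out_fraction, "n_turns": 0,
              "ok": out_fraction <= out_threshold}
        return empty, qc

    arms = codes[idx]
    change = np.flatnonzero(arms[1:] != arms[:-1]) + 1
    events = pd.DataFrame(
        {
            "time_s": t[idx[change]],
            "direction": [
                turn_direction(int(arms[c - 1]), int(arms[c]), convention) for c in change
            ],
            "arm_from": arms[change - 1].astype(np.int64),
            "arm_to": arms[change].astype(np.int64),
        }
    )
    qc = {
        "n_samples": len(track),
        "out_fraction": out_fraction,
        "n_turns": int(len(events)),
        "ok": out_fraction <= out_threshold,
    }
    return events, qc
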