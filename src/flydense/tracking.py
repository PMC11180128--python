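"""Linking triangulated points into per-fly tracks.

Two-pass strategy: crawling flies move a fraction of a millimetre per frame,
while flying or falling flies cover centimetres, so a small search radius
first isolates clean slow tracks; their points are removed and the residual
point cloud is linked again with a larger radius to recover fast tracks.
Assignment within a frame is greedy nearest-neighbor; tracks may bridge up to
``memory`` consecutive missing frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_SLOW_RADIUS = 0.004  # m per frame, crawling (~1 cm/s at 30 fps)
DEFAULT_FAST_RADIUS = 0.060  # m per frame; must cover free-fall from the top
# of the bottle (~1.8 m/s at 30 fps), not just level flight (~0.3 m/s)
DEFAULT_SLOW_SPEED_CUTOFF = 0.02  # m/s, max speed for a track to count as slow
DEFAULT_MEMORY = 3  # frames a track may skip

TRACK_COLUMNS = ["track_id", "class", "frame", "time_s", "x_m", "y_m", "z_m"]


def link(
    points: pd.DataFrame,
    search_radius: float,
    memory: int = DEFAULT_MEMORY,
    start_id: int = 0,
) -> pd.DataFrame:
    """Link points (columns ``frame, time_s, x_m, y_m, z_m``) into tracks.

    Greedy frame-to-frame nearest-neighbor assignment: within each frame,
    candidate (track, point) pairs closer than ``search_radius`` are accepted
    in increasing-distance order; unassigned points start new tracks.  A track
    survives up to ``memory`` frames without a point.  Every input point ends
    up in exactly one track.  Returns a copy with a ``track_id`` column.
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be positive")
    pts = points.sort_values(["frame"], kind="stable").reset_index()
    track_of = np.full(len(pts), -1, dtype=int)
    # active tracks: id -> (last position, last frame)
    active: dict[int, tuple[np.ndarray, int]] = {}
    next_id = start_id
    for frame, grp in pts.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that have been silent too long
        active = {
            tid: (p, f) for tid, (p, f) in active.items() if frame - f <= memory + 1
        }
        idx = grp.index.to_numpy()
        xyz = grp[["x_m", "y_m", "z_m"]].to_numpy()
        cands = []
        for tid, (p, _) in active.items():
            d = np.linalg.norm(xyz - p, axis=1)
            for k in np.nonzero(d <= search_radius)[0]:
                cands.append((d[k], tid, int(idx[k])))
        cands.sort()
        used_tracks: set[int] = set()
        used_points: set[int] = set()
        for d, tid, pi in cands:
            if tid in used_tracks or pi in used_points:
                continue
            used_tracks.add(tid)
            used_points.add(pi)
            track_of[pi] = tid
            active[tid] = (pts.loc[pi, ["x_m", "y_m", "z_m"]].to_numpy(dtype=float), frame)
        for k, pi in enumerate(idx):
            if int(pi) not in used_points:
                track_of[int(pi)] = next_id
                active[next_id] = (xyz[k].astype(float), frame)
                next_id += 1
    out = pts.copy()
    out["track_id"] = track_of
    out = out.set_index("index").sort_index()
    out.index.name = points.index.name
    return out


def track_max_speed(track: pd.DataFrame) -> float:
    """Maximum speed (m/s) between consecutive points of one track."""
    if len(track) < 2:
        return 0.0
    t = track["time_s"].to_numpy()
    p = track[["x_m", "y_m", "z_m"]].to_numpy()
    dt = np.diff(t)
    dt = np.where(dt <= 0, np.nan, dt)
    v = np.linalg.norm(np.diff(p, axis=0), axis=1) / dt
    v = v[np.isfinite(v)]
    return float(v.max()) if len(v) else 0.0


def two_pass_link(
    points: pd.DataFrame,
    slow_radius: float = DEFAULT_SLOW_RADIUS,
    fast_radius: float = DEFAULT_FAST_RADIUS,
    slow_speed_cutoff: float = DEFAULT_SLOW_SPEED_CUTOFF,
    memory: int = DEFAULT_MEMORY,
) -> pd.DataFrame:
    """Two-pass linking: slow crawlers first, then the fast remainder.

    Pass 1 links with ``slow_radius``; tracks with at least two points whose
    maximum speed is <= ``slow_speed_cutoff`` are emitted with class ``slow``
    and their points removed.  Pass 2 links the residual points with
    ``fast_radius`` and emits them as ``fast``.  The union of output points
    equals the input.
    """
    if not slow_radius < fast_radius:
        raise ValueError("slow_radius must be smaller than fast_radius")
    cols = TRACK_COLUMNS
    if points.empty:
        return pd.DataFrame(columns=cols)
    pass1 = link(points, slow_radius, memory=memory)
    slow_ids = []
    for tid, grp in pass1.groupby("track_id"):
        if len(grp) >= 2 and track_max_speed(grp) <= slow_speed_cutoff:
            slow_ids.append(tid)
    slow_mask = pass1["track_id"].isin(slow_ids)
    slow = pass1[slow_mask].copy()
    slow["class"] = "slow"
    residual = points.loc[pass1.index[~slow_mask.to_numpy()]]
    next_id = (int(slow["track_id"].max()) + 1) if len(slow) else 0
    if len(residual):
        fast = link(residual, fast_radius, memory=memory, start_id=next_id)
        fast["class"] = "fast"
        out = pd.concat([slow, fast])
    else:
        out = slow
    out = out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    keep = [c for c in cols if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    return out[keep + extra]
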