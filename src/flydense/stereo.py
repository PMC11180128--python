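"""Two-camera 3D reconstruction of fly detections.

The pipeline mirrors the experiment's processing order: pair frames across
the two unsynchronized cameras by timestamp proximity, discard frames taken
while the bottle was being shaken, triangulate every detection of camera A
against every detection of camera B, and keep only candidate points whose
reprojection error is below a pixel threshold, enforcing one-to-one use of
detections greedily in order of increasing error.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .geometry import CameraModel

#: Default acceptance gate on the mean reprojection error of a candidate point.
DEFAULT_ERROR_THRESHOLD_PX = 3.0

#: Default timestamp tolerance for pairing frames across cameras (10 ms).
DEFAULT_MAX_DT = 0.010

#: Rays closer to parallel than this (degrees) are considered degenerate.
MIN_RAY_ANGLE_DEG = 0.1

POINT_COLUMNS = ["frame", "time_s", "x_m", "y_m", "z_m", "err_px", "det_a", "det_b"]


class DegenerateGeometryError(ValueError):
    """Raised when the two back-projected rays are (near-)parallel."""


def pair_frames(
    detections_a: pd.DataFrame,
    detections_b: pd.DataFrame,
    max_dt: float = DEFAULT_MAX_DT,
) -> pd.DataFrame:
    """Pair camera-A frames with their nearest-in-time camera-B frames.

    Each A frame is matched to at most one B frame with |dt| <= ``max_dt``;
    pairs are disjoint (greedy by increasing |dt|).  Returns a DataFrame with
    columns ``frame_a, frame_b, time_a, time_b, dt`` sorted by ``time_a``.
    Frames without a partner are dropped.
    """
    fa = (
        detections_a[["frame", "time_s"]]
        .drop_duplicates("frame")
        .sort_values("time_s")
        .reset_index(drop=True)
    )
    fb = (
        detections_b[["frame", "time_s"]]
        .drop_duplicates("frame")
        .sort_values("time_s")
        .reset_index(drop=True)
    )
    if fa.empty or fb.empty:
        return pd.DataFrame(columns=["frame_a", "frame_b", "time_a", "time_b", "dt"])
    ta = fa["time_s"].to_numpy()
    tb = fb["time_s"].to_numpy()
    # candidate nearest neighbors on either side of the insertion point
    idx = np.searchsorted(tb, ta)
    cands = []
    for i, t in enumerate(ta):
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < len(tb) and abs(tb[j] - t) <= max_dt + 1e-12:
                cands.append((abs(tb[j] - t), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dt_abs, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(
            (
                fa["frame"].iat[i],
                fb["frame"].iat[j],
                ta[i],
                tb[j],
                tb[j] - ta[i],
            )
        )
    out = pd.DataFrame(pairs, columns=["frame_a", "frame_b", "time_a", "time_b", "dt"])
    return out.sort_values("time_a").reset_index(drop=True)


def reject_shake_frames(pairs: pd.DataFrame, shake_flags: pd.DataFrame) -> pd.DataFrame:
    """Drop frame pairs whose frames fall in a flagged shake interval.

    ``shake_flags`` must have columns ``frame`` and ``shake`` and cover every
    frame referenced by ``pairs``; missing coverage is a configuration error.
    """
    if pairs.empty:
        return pairs
    flags = shake_flags.set_index("frame")["shake"]
    referenced = pd.unique(
        np.concatenate([pairs["frame_a"].to_numpy(), pairs["frame_b"].to_numpy()])
    )
    missing = [f for f in referenced if f not in flags.index]
    if missing:
        raise ValueError(
            f"shake flags missing for {len(missing)} frames (e.g. {missing[:5]})"
        )
    bad = pairs["frame_a"].map(flags).astype(bool) | pairs["frame_b"].map(flags).astype(
        bool
    )
    return pairs[~bad].reset_index(drop=True)


def _pairwise_triangulate(
    pix_a: np.ndarray,
    pix_b: np.ndarray,
    cam_a: CameraModel,
    cam_b: CameraModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triangulate every A-pixel against every B-pixel.

    Returns (points (n,m,3), mean reprojection errors (n,m), ray angles (n,m)
    in degrees).  The 3D point is the midpoint of the common perpendicular of
    the two back-projected rays.
    """
    pix_a = np.atleast_2d(np.asarray(pix_a, dtype=float))
    pix_b = np.atleast_2d(np.asarray(pix_b, dtype=float))
    n, m = len(pix_a), len(pix_b)
    _, da = cam_a.rays(pix_a)  # (n,3) unit
    _, db = cam_b.rays(pix_b)  # (m,3) unit
    oa = cam_a.center
    ob = cam_b.center
    w0 = oa - ob  # (3,)

    b = da @ db.T  # (n,m) = d_a . d_b
    d_dot_w_a = da @ w0  # (n,)
    d_dot_w_b = db @ w0  # (m,)
    denom = 1.0 - b**2
    # closest-approach parameters s (along ray A) and t (along ray B):
    #   s - b t = -da.w0 ;  b s - t = -db.w0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (b * d_dot_w_b[None, :] - d_dot_w_a[:, None]) / denom
        t = (d_dot_w_b[None, :] - b * d_dot_w_a[:, None]) / denom
    pa = oa[None, None, :] + s[..., None] * da[:, None, :]
    pb = ob[None, None, :] + t[..., None] * db[None, :, :]
    points = 0.5 * (pa + pb)

    flat = points.reshape(-1, 3)
    proj_a, depth_a = cam_a.project(flat)
    proj_b, depth_b = cam_b.project(flat)
    err_a = np.linalg.norm(
        proj_a.reshape(n, m, 2) - pix_a[:, None, :], axis=-1
    )
    err_b = np.linalg.norm(
        proj_b.reshape(n, m, 2) - pix_b[None, :, :], axis=-1
    )
    err = 0.5 * (err_a + err_b)
    behind = (depth_a.reshape(n, m) <= 0) | (depth_b.reshape(n, m) <= 0)
    err = np.where(behind, np.inf, err)
    angles = np.degrees(np.arccos(np.clip(np.abs(b), 0.0, 1.0)))
    err = np.where(~np.isfinite(denom) | (denom <= 0), np.inf, err)
    return points, err, angles


def triangulate(
    pix_a: np.ndarray,
    pix_b: np.ndarray,
    cam_a: CameraModel,
    cam_b: CameraModel,
) -> tuple[np.ndarray, float]:
    """Triangulate one detection pair.

    Returns (3D point in the bottle frame, mean reprojection error in pixels).
    Raises :class:`DegenerateGeometryError` for near-parallel rays.
    """
    points, err, angles = _pairwise_triangulate(
        np.atleast_2d(pix_a), np.atleast_2d(pix_b), cam_a, cam_b
    )
    if angles[0, 0] < MIN_RAY_ANGLE_DEG:
        raise DegenerateGeometryError(
            f"ray angle {angles[0, 0]:.4f} deg below {MIN_RAY_ANGLE_DEG} deg"
        )
    return points[0, 0], float(err[0, 0])


def match_all_pairs(
    pix_a: np.ndarray,
    pix_b: np.ndarray,
    cam_a: CameraModel,
    cam_b: CameraModel,
    error_threshold_px: float = DEFAULT_ERROR_THRESHOLD_PX,
) -> pd.DataFrame:
    """Exhaustive candidate matching for one frame pair.

    Triangulates every AxB candidate, keeps those with reprojection error at
    or below the threshold, and resolves conflicts greedily in increasing
    error order so that each detection is used at most once.  Returns a
    DataFrame with columns ``x_m, y_m, z_m, err_px, det_a, det_b`` sorted by
    error.
    """
    pix_a = np.atleast_2d(np.asarray(pix_a, dtype=float))
    pix_b = np.atleast_2d(np.asarray(pix_b, dtype=float))
    cols = ["x_m", "y_m", "z_m", "err_px", "det_a", "det_b"]
    if pix_a.size == 0 or pix_b.size == 0:
        return pd.DataFrame(columns=cols)
    points, err, angles = _pairwise_triangulate(pix_a, pix_b, cam_a, cam_b)
    err = np.where(angles < MIN_RAY_ANGLE_DEG, np.inf, err)
    ia, ib = np.nonzero(err <= error_threshold_px)
    order = np.argsort(err[ia, ib], kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for k in order:
        i, j = int(ia[k]), int(ib[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        p = points[i, j]
        rows.append((p[0], p[1], p[2], float(err[i, j]), i, j))
    return pd.DataFrame(rows, columns=cols)


def min_cost_match(
    pix_a: np.ndarray,
    pix_b: np.ndarray,
    cam_a: CameraModel,
    cam_b: CameraModel,
    error_threshold_px: float = DEFAULT_ERROR_THRESHOLD_PX,
) -> pd.DataFrame:
    """Reference matcher: optimal one-to-one assignment minimizing total error.

    Used as an independent cross-check of :func:`match_all_pairs`; not part of
    the production path.
    """
    from scipy.optimize import linear_sum_assignment

    pix_a = np.atleast_2d(np.asarray(pix_a, dtype=float))
    pix_b = np.atleast_2d(np.asarray(pix_b, dtype=float))
    cols = ["x_m", "y_m", "z_m", "err_px", "det_a", "det_b"]
    if pix_a.size == 0 or pix_b.size == 0:
        return pd.DataFrame(columns=cols)
    points, err, angles = _pairwise_triangulate(pix_a, pix_b, cam_a, cam_b)
    err = np.where(angles < MIN_RAY_ANGLE_DEG, np.inf, err)
    # large-but-finite cost for inadmissible candidates, then filter after solving
    big = 1e6
    cost = np.where(err <= error_threshold_px, err, big)
    ri, ci = linear_sum_assignment(cost)
    rows = []
    for i, j in zip(ri, ci):
        if cost[i, j] >= big:
            continue
        p = points[i, j]
        rows.append((p[0], p[1], p[2], float(err[i, j]), int(i), int(j)))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("err_px", kind="stable").reset_index(drop=True)


def reconstruct(
    detections_a: pd.DataFrame,
    detections_b: pd.DataFrame,
    cam_a: CameraModel,
    cam_b: CameraModel,
    shake_flags: pd.DataFrame | None = None,
    max_dt: float = DEFAULT_MAX_DT,
    error_threshold_px: float = DEFAULT_ERROR_THRESHOLD_PX,
    bottle=None,
    containment_dilation_m: float = 0.01,
) -> pd.DataFrame:
    """Full reconstruction: frame pairing, shake rejection, per-pair matching.

    If ``bottle`` (a :class:`~flydense.geometry.BottleGeometry`) is given,
    accepted points are additionally required to lie inside the bottle box
    dilated by ``containment_dilation_m`` — flies live in the bottle, so
    anything outside is a ghost match.  Returns a points DataFrame with
    columns ``frame, time_s, x_m, y_m, z_m, err_px, det_a, det_b`` where
    ``det_a``/``det_b`` index into the input detection tables.
    """
    pairs = pair_frames(detections_a, detections_b, max_dt=max_dt)
    if shake_flags is not None:
        pairs = reject_shake_frames(pairs, shake_flags)
    by_frame_a = {f: g for f, g in detections_a.groupby("frame")}
    by_frame_b = {f: g for f, g in detections_b.groupby("frame")}
    chunks = []
    for row in pairs.itertuples(index=False):
        ga = by_frame_a.get(row.frame_a)
        gb = by_frame_b.get(row.frame_b)
        if ga is None or gb is None or ga.empty or gb.empty:
            continue
        matched = match_all_pairs(
            ga[["x_px", "y_px"]].to_numpy(),
            gb[["x_px", "y_px"]].to_numpy(),
            cam_a,
            cam_b,
            error_threshold_px=error_threshold_px,
        )
        if matched.empty:
            continue
        matched = matched.copy()
        matched["det_a"] = ga.index.to_numpy()[matched["det_a"].to_numpy()]
        matched["det_b"] = gb.index.to_numpy()[matched["det_b"].to_numpy()]
        matched.insert(0, "time_s", row.time_a)
        matched.insert(0, "frame", row.frame_a)
        chunks.append(matched)
    if not chunks:
        return pd.DataFrame(columns=POINT_COLUMNS)
    out = pd.concat(chunks, ignore_index=True)
    out = out[POINT_COLUMNS]
    if bottle is not None and len(out):
        inside = bottle.contains(
            out[["x_m", "y_m", "z_m"]].to_numpy(), dilation=containment_dilation_m
        )
        out = out[inside].reset_index(drop=True)
    return out
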