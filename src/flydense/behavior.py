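"""Behavior-stage classification of 3D fly tracks.

Tracks are segmented into maximal runs of a single wall state (on the floor,
on a wall/ceiling, or in free space).  Surface runs are further split into
immobile and moving stretches and labeled A (immobile), B (walking) or
C (climbing: moving on a side wall with net upward progress).  Free-space
runs are first screened by the rapid-movement filter (stationary
mislocalized points masquerading as airborne flies are discarded), then fit
with a ballistic model z(t) = z0 + vz t - 1/2 g_eff t^2:

* a good parabolic fit with g_eff near g is a jump/fall (D),
* a good fit with g_eff well below g is an assisted jump — wing thrust
  subtracts from gravity (E),
* a poor parabolic fit, or g_eff indistinguishable from zero, is powered
  flight (F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import BottleGeometry

GRAVITY = 9.80665

#: g_eff below ``G_BAND[0]`` * g means thrust ~cancels gravity (flight);
#: between the band edges is assisted jumping; above is a plain jump/fall.
G_BAND = (0.2, 0.8)

DEFAULT_RESIDUAL_FRACTION = 0.15  # of the segment's vertical extent
DEFAULT_MIN_FREE_FRAMES = 4
DEFAULT_MIN_SPEED = 0.05  # m/s, rapid-movement filter for free-space segments
DEFAULT_UPPER_FRACTION = 0.5
DEFAULT_BODY_LENGTH = 0.0025  # m

EVENT_COLUMNS = [
    "track_id",
    "t_start",
    "t_end",
    "stage",
    "g_eff",
    "v0",
    "rms_residual",
    "n_frames",
]


@dataclass(frozen=True)
class BallisticFit:
    """Least-squares ballistic fit of a free-space segment."""

    g_eff: float  # estimated vertical deceleration, m/s^2
    v0: float  # speed at segment start, m/s
    rms_residual: float  # pooled over the three axes, m
    n_frames: int
    z_extent: float  # max(z) - min(z) over the segment, m
    g_eff_se: float = 0.0  # standard error of g_eff from the fit covariance
    vz0: float = 0.0  # fitted vertical velocity at segment start, m/s
    vz1: float = 0.0  # fitted vertical velocity at segment end, m/s

    def __post_init__(self) -> None:
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


def classify_wall(
    point: np.ndarray, bottle: BottleGeometry, margin: float | None = None
) -> str:
    """'on_floor', 'on_wall' or 'free_space' for a single point."""
    return bottle.surface_class(point, margin)


def fit_ballistic(times: np.ndarray, positions: np.ndarray) -> BallisticFit:
    """Fit z quadratically and x, y linearly in time; closed-form least squares.

    ``g_eff`` is minus twice the quadratic coefficient of z(t), i.e. the
    effective vertical deceleration.  The residual is the RMS over all three
    axes' residuals.  Requires at least 4 frames.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)
    if len(t) < 4:
        raise ValueError(f"ballistic fit needs >= 4 frames, got {len(t)}")
    if np.ptp(t) <= 0:
        raise ValueError("all segment times are equal")
    tc = t - t[0]
    cz = np.polyfit(tc, p[:, 2], 2)
    cx = np.polyfit(tc, p[:, 0], 1)
    cy = np.polyfit(tc, p[:, 1], 1)
    res_z = p[:, 2] - np.polyval(cz, tc)
    res = np.concatenate(
        [p[:, 0] - np.polyval(cx, tc), p[:, 1] - np.polyval(cy, tc), res_z]
    )
    rms = float(np.sqrt(np.mean(res**2)))
    g_eff = float(-2.0 * cz[0])
    # standard error of the quadratic coefficient from the fit covariance
    dof = max(len(t) - 3, 1)
    sigma2 = float(res_z @ res_z) / dof
    design = np.vander(tc, 3)
    cov00 = np.linalg.inv(design.T @ design)[0, 0]
    g_eff_se = 2.0 * float(np.sqrt(sigma2 * cov00))
    v0 = float(np.sqrt(cx[0] ** 2 + cy[0] ** 2 + cz[1] ** 2))
    return BallisticFit(
        g_eff=g_eff,
        v0=v0,
        rms_residual=rms,
        n_frames=len(t),
        z_extent=float(np.ptp(p[:, 2])),
        g_eff_se=g_eff_se,
        vz0=float(cz[1]),
        vz1=float(2.0 * cz[0] * tc[-1] + cz[1]),
    )


def classify_free_event(
    fit: BallisticFit,
    g: float = GRAVITY,
    residual_fraction: float = DEFAULT_RESIDUAL_FRACTION,
) -> str:
    """Label a free-space segment D (jump/fall), E (assisted jump) or F (flight)."""
    if fit.rms_residual > residual_fraction * fit.z_extent or fit.g_eff <= G_BAND[0] * g:
        return "F"
    if fit.g_eff < G_BAND[1] * g:
        return "E"
    return "D"


def classify_on_wall_event(
    positions: np.ndarray,
    wall_state: str,
    body_length: float = DEFAULT_BODY_LENGTH,
) -> str:
    """Label a surface segment A (immobile), B (walking) or C (climbing).

    Net displacement below one body length is immobile.  Displacement on a
    side wall with net upward progress is climbing; everything else that
    moves (floor, ceiling, or downward wall motion) is walking.
    """
    p = np.asarray(positions, dtype=float)
    net = float(np.linalg.norm(p[-1] - p[0]))
    if net < body_length:
        return "A"
    if wall_state == "on_wall" and (p[-1, 2] - p[0, 2]) > 0:
        return "C"
    return "B"


def rapid_motion_filter(
    segments: list[pd.DataFrame], min_speed: float = DEFAULT_MIN_SPEED
) -> list[pd.DataFrame]:
    """Discard free-space segments whose maximum inter-frame speed is below
    ``min_speed`` — these are mislocalized wall points, not airborne flies."""
    kept = []
    for seg in segments:
        if len(seg) < 2:
            continue
        t = seg["time_s"].to_numpy()
        p = seg[["x_m", "y_m", "z_m"]].to_numpy()
        dt = np.diff(t)
        dt = np.where(dt <= 0, np.nan, dt)
        v = np.linalg.norm(np.diff(p, axis=0), axis=1) / dt
        v = v[np.isfinite(v)]
        if len(v) and v.max() >= min_speed:
            kept.append(seg)
    return kept


def activity_count(
    points: pd.DataFrame,
    bottle: BottleGeometry,
    upper_fraction: float = DEFAULT_UPPER_FRACTION,
) -> pd.DataFrame:
    """Per-frame count of points in the upper portion of the bottle.

    This is the automatic activity metric: flies climbing high on the walls.
    Returns a DataFrame ``frame, count`` covering the full frame range of the
    input (zeros where no point qualifies).
    """
    if not (0.0 < upper_fraction < 1.0):
        raise ValueError("upper_fraction must be in (0, 1)")
    z_gate = (1.0 - upper_fraction) * bottle.height
    if points.empty:
        return pd.DataFrame({"frame": [], "count": []}).astype(
            {"frame": int, "count": int}
        )
    high = points[points["z_m"] >= z_gate]
    counts = high.groupby("frame").size()
    frames = np.arange(points["frame"].min(), points["frame"].max() + 1)
    out = counts.reindex(frames, fill_value=0)
    return pd.DataFrame({"frame": frames, "count": out.to_numpy()})


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of equal labels."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i))
            start = i
    return runs


def _moving_mask(
    times: np.ndarray,
    positions: np.ndarray,
    body_length: float,
    window_s: float = 1.0,
) -> np.ndarray:
    """Per-frame flag: did the fly cover >= one body length in the trailing window?

    Positions are median-filtered over 3 frames first so that a single
    mislocalized point cannot fake a walking onset.
    """
    n = len(times)
    if n >= 3:
        from scipy.ndimage import median_filter

        positions = median_filter(positions, size=(3, 1), mode="nearest")
    moving = np.zeros(n, dtype=bool)
    j = 0
    for i in range(n):
        while times[i] - times[j] > window_s:
            j += 1
        ref = max(j - 1, 0) if j > 0 else 0
        disp = np.linalg.norm(positions[i] - positions[ref])
        moving[i] = disp >= body_length
    return moving


#: Largest thrust acceleration a fly can plausibly produce (about 1.5 g).
#: Anything airborne obeys a = thrust - g, so the implied thrust
#: |a_observed + g z| beyond this bound marks a linking artifact (identity
#: swap between flies) or an unobserved surface contact, and the run is split.
MAX_PLAUSIBLE_THRUST = 15.0  # m/s^2


def _split_free_run(
    times: np.ndarray, positions: np.ndarray, bottle: BottleGeometry
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a free-space run at kinematically impossible accelerations and at
    temporal gaps adjacent to near-surface points.

    Gravity plus wing thrust bounds the acceleration of anything airborne;
    a discrete acceleration whose implied thrust is far beyond that bound
    means the run stitches two different arcs together (an identity swap
    between flies, or two jumps fused across missing frames) and must not be
    fit as one trajectory.
    """
    n = len(times)
    if n < 3:
        return [(times, positions)]
    dt = np.diff(times)
    vel = np.diff(positions, axis=0) / dt[:, None]
    dv = np.diff(vel, axis=0)
    mid_dt = 0.5 * (dt[:-1] + dt[1:])
    accel_vec = dv / mid_dt[:, None]
    accel_vec[:, 2] += GRAVITY  # implied thrust = observed accel + g
    accel = np.linalg.norm(accel_vec, axis=1)
    gap = dt > 1.5 * np.median(dt)
    dist = np.minimum.reduce(
        [
            positions[:, 2],
            bottle.height - positions[:, 2],
            bottle.width / 2 - np.abs(positions[:, 0]),
            bottle.depth / 2 - np.abs(positions[:, 1]),
        ]
    )
    near = dist < 2.0 * bottle.wall_margin
    cut_set = set()
    for i in range(len(dt)):
        if gap[i] and (near[i] or near[i + 1]):
            cut_set.add(i + 1)
    for i in range(len(accel)):
        if accel[i] > MAX_PLAUSIBLE_THRUST:
            # the velocity change straddles point i+1; cut the run there
            cut_set.add(i + 1)
    cuts = [0] + sorted(cut_set) + [n]
    return [
        (times[c0:c1], positions[c0:c1]) for c0, c1 in zip(cuts[:-1], cuts[1:])
    ]


def _reject_spikes(
    times: np.ndarray, positions: np.ndarray, abs_floor: float = 0.003
) -> tuple[np.ndarray, np.ndarray]:
    """Drop gross outliers (identity-swap spikes) from a free segment.

    Points whose fit residual exceeds both ``abs_floor`` (m) and four times
    the median residual are removed, at most 20% of the segment.  Clean
    segments pass through untouched, so exact fits stay exact.
    """
    if len(times) < 5:
        return times, positions
    fit0 = fit_ballistic(times, positions)
    tc = times - times[0]
    res = np.column_stack(
        [
            positions[:, 0] - np.polyval(np.polyfit(tc, positions[:, 0], 1), tc),
            positions[:, 1] - np.polyval(np.polyfit(tc, positions[:, 1], 1), tc),
            positions[:, 2] - np.polyval(np.polyfit(tc, positions[:, 2], 2), tc),
        ]
    )
    r = np.linalg.norm(res, axis=1)
    med = np.median(r)
    bad = (r > abs_floor) & (r > 4.0 * med)
    if bad.sum() == 0 or bad.sum() > 0.2 * len(times):
        return times, positions
    return times[~bad], positions[~bad]


def _classify_free_segment(
    seg_t: np.ndarray,
    seg_p: np.ndarray,
    min_speed: float,
    min_free_frames: int,
    residual_fraction: float,
    g: float,
    g_se_max: float,
    min_curvature_frames: int,
    min_jump_vz: float,
    residual_abs_max: float = 0.003,
    min_flight_frames: int = 10,
) -> dict | None:
    """Vet and classify one free-space segment; None if no event is emitted."""
    if len(seg_t) < max(2, min_free_frames):
        return None
    seg_df = pd.DataFrame(
        {
            "time_s": seg_t,
            "x_m": seg_p[:, 0],
            "y_m": seg_p[:, 1],
            "z_m": seg_p[:, 2],
        }
    )
    if not rapid_motion_filter([seg_df], min_speed=min_speed):
        return None
    seg_t, seg_p = _reject_spikes(seg_t, seg_p)
    if len(seg_t) < min_free_frames:
        return None
    fit = fit_ballistic(seg_t, seg_p)
    if fit.n_frames < min_curvature_frames:
        # too short to either certify a deviation from a parabola or to
        # measure its curvature
        return None
    # a genuine ballistic arc fits to localization-noise level, so the
    # relative criterion is capped by an absolute one for large arcs
    parabola_ok = (
        fit.rms_residual <= residual_fraction * fit.z_extent
        and fit.rms_residual <= residual_abs_max
    )
    if parabola_ok and fit.g_eff_se > g_se_max:
        return None
    if not parabola_ok:
        # powered flight is sustained; a sub-second non-parabolic snippet is
        # within the corruption modes of stereo tracking, not evidence of
        # flight
        if fit.n_frames < min_flight_frames:
            return None
        dt = np.diff(seg_t)
        steps = np.diff(seg_p, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        speeds = norms / np.where(dt <= 0, np.nan, dt)
        if np.nanmedian(speeds) < min_speed:
            return None
        big = norms > 1e-3  # direction is meaningless below noise scale
        units = steps[big] / norms[big, None]
        if len(units) < 3:
            return None
        persistence = float(np.mean(np.sum(units[1:] * units[:-1], axis=1)))
        if persistence < 0.2:
            return None
        stage = "F"
    else:
        stage = classify_free_event(fit, g=g, residual_fraction=residual_fraction)
        if stage == "F" and fit.g_eff + 2.0 * fit.g_eff_se > G_BAND[0] * g:
            # curvature not confidently below the lower band edge: an
            # assisted jump drawn near the edge, not thrust-canceled flight
            stage = "E" if fit.g_eff < G_BAND[1] * g else "D"
        if stage in ("D", "E") and max(abs(fit.vz0), abs(fit.vz1)) < min_jump_vz:
            # a ballistic arc is launched (or lands) fast; slow vertical
            # motion throughout is a hover/flight fragment
            return None
    return {
        "track_id": -1,
        "t_start": float(seg_t[0]),
        "t_end": float(seg_t[-1]),
        "stage": stage,
        "g_eff": fit.g_eff,
        "v0": fit.v0,
        "rms_residual": fit.rms_residual,
        "n_frames": fit.n_frames,
    }


def classify_track(
    track: pd.DataFrame,
    bottle: BottleGeometry,
    body_length: float = DEFAULT_BODY_LENGTH,
    min_speed: float = DEFAULT_MIN_SPEED,
    min_free_frames: int = DEFAULT_MIN_FREE_FRAMES,
    residual_fraction: float = DEFAULT_RESIDUAL_FRACTION,
    g: float = GRAVITY,
    g_se_max: float = 1.5,
    min_curvature_frames: int = 6,
    min_jump_vz: float = 0.45,
    min_surface_frames: int = 8,
) -> list[dict]:
    """Classify one track into a list of behavior events.

    Surface runs are split at immobile/moving boundaries before A/B/C
    labeling so that the onset of walking is resolved in time; free-space
    runs shorter than ``min_free_frames`` or failing the rapid-movement
    filter produce no event.

    Segments that deviate strongly from a parabola are powered flight,
    provided they are also *continuously* fast (median inter-frame speed at
    or above ``min_speed``) and directionally smooth (consecutive
    displacement vectors mostly agree in direction) — a mostly-stationary
    or zigzagging segment with a large residual is a linking artifact
    (identity swaps between nearby flies), not a flying fly.  Parabola-consistent
    segments are only given a curvature-based label (D, E, or hover-like F)
    when the curvature is actually measurable: at least
    ``min_curvature_frames`` frames and a g_eff standard error below
    ``g_se_max`` (m/s^2).  Ballistic labels (D/E) additionally require an
    impulsive initial vertical speed of at least ``min_jump_vz`` (m/s),
    since a jump is a launch.
    """
    t = track["time_s"].to_numpy()
    p = track[["x_m", "y_m", "z_m"]].to_numpy()
    tid = track["track_id"].iat[0] if "track_id" in track.columns else -1
    states = np.array([bottle.surface_class(pt) for pt in p])
    events: list[dict] = []
    for a, b in _runs(states):
        seg_t, seg_p = t[a:b], p[a:b]
        state = states[a]
        if state == "free_space":
            for sub_t, sub_p in _split_free_run(seg_t, seg_p, bottle):
                event = _classify_free_segment(
                    sub_t,
                    sub_p,
                    min_speed=min_speed,
                    min_free_frames=min_free_frames,
                    residual_fraction=residual_fraction,
                    g=g,
                    g_se_max=g_se_max,
                    min_curvature_frames=min_curvature_frames,
                    min_jump_vz=min_jump_vz,
                )
                if event is not None:
                    event["track_id"] = tid
                    events.append(event)
        else:
            # landing/takeoff frames of an arc can sit inside the wall margin
            # while still moving fast; the implied-thrust split severs those
            # slivers from genuine surface behavior
            for seg_t, seg_p in _split_free_run(seg_t, seg_p, bottle):
                events.extend(
                    _classify_surface_run(
                        seg_t, seg_p, state, tid, body_length, min_surface_frames
                    )
                )
    return events


def _classify_surface_run(
    seg_t: np.ndarray,
    seg_p: np.ndarray,
    state: str,
    tid,
    body_length: float,
    min_surface_frames: int,
) -> list[dict]:
    """Split a surface run into immobile/moving stretches and label them."""
    events: list[dict] = []
    if len(seg_t) == 0:
        return events
    moving = _moving_mask(seg_t, seg_p, body_length)
    for c, d in _runs(moving):
        sub_t, sub_p = seg_t[c:d], seg_p[c:d]
        if not moving[c]:
            stage = "A"
        else:
            # walking/climbing is sustained and directed; a brief or
            # zigzagging "moving" run is linker cross-talk between
            # nearby flies, not a behavior
            if d - c < min_surface_frames:
                continue
            path = float(np.sum(np.linalg.norm(np.diff(sub_p, axis=0), axis=1)))
            net = float(np.linalg.norm(sub_p[-1] - sub_p[0]))
            if path > 0 and net / path < 0.2:
                continue
            stage = classify_on_wall_event(sub_p, state, body_length)
        events.append(
            {
                "track_id": tid,
                "t_start": float(sub_t[0]),
                "t_end": float(sub_t[-1]),
                "stage": stage,
                "g_eff": np.nan,
                "v0": np.nan,
                "rms_residual": np.nan,
                "n_frames": int(d - c),
            }
        )
    return events


def classify_tracks(
    tracks: pd.DataFrame,
    bottle: BottleGeometry,
    **kwargs,
) -> pd.DataFrame:
    """Classify all tracks; returns the events table (one row per event)."""
    events: list[dict] = []
    if tracks.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    for _, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("time_s")
        events.extend(classify_track(grp, bottle, **kwargs))
    if not events:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.DataFrame(events, columns=EVENT_COLUMNS)
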