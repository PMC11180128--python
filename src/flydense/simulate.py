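"""Synthetic flight-assay generator.

Emulates the experiment end to end so that every downstream stage can be
exercised without the multi-terabyte raw videos: an O2 time course (rapid
flush with He or N2, then first-order re-entry of ambient air), flies that
move through behavior stages gated by O2 availability and gas density, and
noisy detections from two desynchronized pinhole cameras watching the bottle.

Behavior stages (ground truth ``stage`` column):

* ``A`` — immobile (O2-deprivation shock) whenever pO2 is below the activity
  gate.
* ``B`` — walking on the floor toward a wall.
* ``C`` — climbing a side wall.
* ``D`` — ballistic jump from a wall (vertical deceleration g); only occurs
  while the gas density is below the flight-density gate.
* ``E`` — assisted jump: wing thrust subtracts from gravity, so the arc is
  still parabolic but with an effective deceleration drawn uniformly from
  (0.2 g, 0.8 g); also restricted to sub-gate densities.
* ``F`` — powered flight with non-constant acceleration (a curved approach,
  a sinusoidal hover loop, and a landing leg); only occurs at or above the
  flight-density gate.

Because density in an N2 flush never drops much below ambient, N2 runs never
produce stages D or E — flies go straight from climbing to flight, the key
asymmetry the assay is built to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gas import AIR, component_density, get_species
from .geometry import BottleGeometry, CameraModel

GRAVITY = 9.80665

#: First-order air re-entry rates (1/s).  Helium leaks out of the bottle much
#: faster than nitrogen, so its default recovery rate is higher.
DEFAULT_RECOVERY_RATES = {"He": 0.010, "N2": 0.005}

GROUND_TRUTH_COLUMNS = [
    "fly_id",
    "frame",
    "time_s",
    "x_m",
    "y_m",
    "z_m",
    "stage",
    "shake",
]
DETECTION_COLUMNS = ["camera_id", "frame", "time_s", "x_px", "y_px", "confidence"]


@dataclass(frozen=True)
class O2Series:
    """O2 partial-pressure time series (times s, strictly increasing; pO2 mbar)."""

    times: np.ndarray
    po2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.po2, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "po2", p)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and po2 must be 1-D arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(p < -1e-9):
            raise ValueError("pO2 must be non-negative")

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation, clamped at the series endpoints."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.po2)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "po2_mbar": self.po2})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "O2Series":
        return cls(df["time_s"].to_numpy(), df["po2_mbar"].to_numpy())


@dataclass(frozen=True)
class SimConfig:
    """All tunable knobs of the synthetic assay.

    Stage gating mirrors the experiment: ``activity_pO2_threshold`` (mbar) is
    the O2 level above which flies move at all; ``flight_density_threshold``
    (kg/m^3) is the gas density at which powered flight becomes possible.
    """

    n_flies: int = 4
    frame_rate: float = 30.0
    duration: float = 180.0
    seed: int = 0
    pixel_noise_sd: float = 0.5
    dropout_rate: float = 0.05
    false_positive_rate: float = 0.2
    sync_jitter_max: float = 0.010
    shake_period: float = 60.0
    shake_duration: float = 1.0
    activity_pO2_threshold: float = 33.0
    flight_density_threshold: float = 0.93
    jump_speed: float = 0.8
    flight_speed: float = 0.3
    body_length: float = 0.0025
    walk_speed: float = 0.010
    climb_speed: float = 0.012
    jump_hazard: float = 0.03
    flight_hazard: float = 0.05
    flight_duration: float = 1.5
    o2_flush_duration: float = 20.0
    o2_sample_interval: float = 1.0
    o2_recovery_rate: float | None = None

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "jump_hazard", "flight_hazard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be non-negative")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.activity_pO2_threshold <= 0 or self.flight_density_threshold <= 0:
            raise ValueError("gating thresholds must be positive")
        if self.n_flies < 0:
            raise ValueError("n_flies must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_o2_timecourse(
    flush_species: str = "He",
    flush_duration: float = 20.0,
    recovery_rate: float | None = None,
    duration: float = 180.0,
    ambient_pO2: float = 210.0,
    sample_interval: float = 1.0,
    seed: int | None = None,
) -> O2Series:
    """Closed-form flush-and-recovery O2 time course.

    During the flush ([0, flush_duration]) pO2 decays exponentially from
    ambient to 1 mbar; afterwards it relaxes first-order toward ambient at
    ``recovery_rate`` (species default: He recovers faster than N2).  The
    series is deterministic; ``seed`` is accepted for interface symmetry.
    """
    if duration <= 0 or flush_duration <= 0:
        raise ValueError("durations must be positive")
    species = get_species(flush_species)
    if recovery_rate is None:
        recovery_rate = DEFAULT_RECOVERY_RATES[species.name]
    if recovery_rate <= 0:
        raise ValueError("recovery_rate must be positive")
    times = np.arange(0.0, duration + 1e-9, sample_interval)
    p_end = 1.0  # mbar at end of flush
    k_flush = math.log(ambient_pO2 / p_end) / flush_duration
    po2 = np.where(
        times <= flush_duration,
        ambient_pO2 * np.exp(-k_flush * times),
        ambient_pO2 - (ambient_pO2 - p_end)
        * np.exp(-recovery_rate * (times - flush_duration)),
    )
    return O2Series(times, po2)


def o2_recovery_time(
    target_po2: float,
    recovery_rate: float,
    flush_duration: float = 20.0,
    ambient_pO2: float = 210.0,
) -> float:
    """Time (s) at which the recovery branch reaches ``target_po2`` (closed form)."""
    p_end = 1.0
    if not (p_end <= target_po2 < ambient_pO2):
        raise ValueError("target_po2 must lie in the recovery range")
    return flush_duration + math.log(
        (ambient_pO2 - p_end) / (ambient_pO2 - target_po2)
    ) / recovery_rate


def shake_flags(times: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Boolean mask of frames falling inside the periodic shake windows."""
    times = np.asarray(times, dtype=float)
    if cfg.shake_period <= 0 or cfg.shake_duration <= 0:
        return np.zeros(times.shape, dtype=bool)
    return (times % cfg.shake_period) < cfg.shake_duration


def _smoothstep(s: float) -> float:
    s = min(max(s, 0.0), 1.0)
    return s * s * (3.0 - 2.0 * s)


class _FlightPath:
    """Closed-form powered-flight trajectory: approach, hover loop, landing.

    The hover loop superposes a horizontal ellipse and a vertical sinusoid, so
    the best-fitting parabola leaves a large residual by construction.  The
    vertical oscillation is gentle (|z''| well below g): lift roughly cancels
    weight in hovering flight, which also means no sub-window of the path has
    the curvature of a ballistic arc.
    """

    APPROACH_T = 0.3
    LAND_T = 0.3
    AMP_Z = 0.03
    FREQ_Z = 1.0
    R_X = 0.025
    R_Y = 0.012
    OMEGA = 2.0 * math.pi * 0.8

    def __init__(
        self,
        p0: np.ndarray,
        t0: float,
        loiter_T: float,
        bottle: BottleGeometry,
        rng: np.random.Generator,
    ) -> None:
        self.p0 = p0.copy()
        self.t0 = t0
        self.loiter_T = loiter_T
        hw, hd, h = bottle.width / 2, bottle.depth / 2, bottle.height
        # the loop extends by 2*R_X toward -x and +-R_Y in y from its start
        # point; draw the start so the whole loop clears the walls
        clear = 2.5 * bottle.wall_margin
        x_lo, x_hi = -hw + clear + 2 * self.R_X, hw - clear
        y_lo, y_hi = -hd + clear + self.R_Y, hd - clear - self.R_Y
        if x_lo >= x_hi or y_lo >= y_hi:
            raise ValueError("bottle too small for the default flight loop")
        self.c = np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)])
        self.z_mid = float(np.clip(p0[2] + 0.03, 0.08, h - 0.08))
        # loiter end point, used to pick the landing wall
        u = loiter_T
        xy_end = self.c + np.array(
            [self.R_X * (math.cos(self.OMEGA * u) - 1.0),
             self.R_Y * math.sin(self.OMEGA * u)]
        )
        z_end = self.z_mid + self.AMP_Z * math.sin(2 * math.pi * self.FREQ_Z * u)
        axis = 0 if abs(xy_end[0]) / hw >= abs(xy_end[1]) / hd else 1
        sign = 1.0 if xy_end[axis] >= 0 else -1.0
        half = hw if axis == 0 else hd
        land = np.array([xy_end[0], xy_end[1], float(np.clip(z_end, 0.03, h - 0.03))])
        land[axis] = sign * (half - 0.001)
        self.p_loiter_end = np.array([xy_end[0], xy_end[1], z_end])
        self.land_point = land
        self.land_axis = axis
        self.land_sign = sign

    @property
    def total_T(self) -> float:
        return self.APPROACH_T + self.loiter_T + self.LAND_T

    def position(self, tau: float) -> np.ndarray:
        if tau <= self.APPROACH_T:
            s = _smoothstep(tau / self.APPROACH_T)
            xy = self.p0[:2] + (self.c - self.p0[:2]) * s
            z = self.p0[2] + (self.z_mid - self.p0[2]) * s
            return np.array([xy[0], xy[1], z])
        u = tau - self.APPROACH_T
        if u <= self.loiter_T:
            xy = self.c + np.array(
                [self.R_X * (math.cos(self.OMEGA * u) - 1.0),
                 self.R_Y * math.sin(self.OMEGA * u)]
            )
            z = self.z_mid + self.AMP_Z * math.sin(2 * math.pi * self.FREQ_Z * u)
            return np.array([xy[0], xy[1], z])
        s = _smoothstep((u - self.loiter_T) / self.LAND_T)
        return self.p_loiter_end + (self.land_point - self.p_loiter_end) * s


def simulate_flies(
    cfg: SimConfig,
    o2: O2Series,
    bottle: BottleGeometry | None = None,
    flush_species: str = "He",
    ambient_pO2: float = 210.0,
    ref_temperature: float = 273.15,
    ref_pressure: float = 1013.25,
) -> pd.DataFrame:
    """Simulate ground-truth fly trajectories and behavior stages.

    Returns a DataFrame with columns ``fly_id, frame, time_s, x_m, y_m, z_m,
    stage, shake``.  Deterministic for a fixed config.
    """
    bottle = bottle or BottleGeometry()
    rng = np.random.default_rng([cfg.seed, 0])
    n_frames = int(round(cfg.duration * cfg.frame_rate))
    dt = 1.0 / cfg.frame_rate
    times = np.arange(n_frames) * dt
    po2_t = o2.interp(times)
    species = get_species(flush_species)
    rho_air = component_density(AIR, ref_temperature, ref_pressure)
    rho_flush = component_density(species, ref_temperature, ref_pressure)
    frac = np.clip(po2_t / ambient_pO2, 0.0, 1.0)
    rho_t = frac * rho_air + (1.0 - frac) * rho_flush
    shakes = shake_flags(times, cfg)

    hw, hd, h = bottle.width / 2, bottle.depth / 2, bottle.height
    eps = 0.001  # standoff of a fly's centroid from the surface it sits on
    z_cap = h - 0.03  # climbers stop their steady ascent here

    rows: list[tuple] = []
    for fly in range(cfg.n_flies):
        pos = np.array(
            [rng.uniform(-0.8 * hw, 0.8 * hw), rng.uniform(-0.8 * hd, 0.8 * hd), eps]
        )
        mode = "A"
        wall_axis, wall_sign = 0, 1.0
        walk_target = np.zeros(2)
        lateral_dir = 1.0
        arc: dict | None = None
        flight: _FlightPath | None = None

        for i in range(n_frames):
            t = times[i]
            po2 = po2_t[i]
            rho = rho_t[i]

            if mode in ("A", "B", "C"):
                if po2 < cfg.activity_pO2_threshold:
                    mode = "A"
                elif mode == "A":
                    mode = "B"
                    walk_target, wall_axis, wall_sign = _pick_wall_target(
                        rng, pos, hw, hd
                    )

            if mode == "B":
                delta = walk_target - pos[:2]
                dist = float(np.linalg.norm(delta))
                if dist < 0.002:
                    mode = "C"
                    pos[wall_axis] = wall_sign * ((hw if wall_axis == 0 else hd) - eps)
                    lateral_dir = 1.0 if rng.random() < 0.5 else -1.0
                else:
                    step = min(cfg.walk_speed * dt, dist)
                    jitter = rng.normal(0.0, 5e-5, 2)
                    pos[:2] += delta / dist * step + jitter
                    pos[0] = np.clip(pos[0], -hw + eps, hw - eps)
                    pos[1] = np.clip(pos[1], -hd + eps, hd - eps)
                    pos[2] = eps

            elif mode == "C":
                started_event = False
                if rho < cfg.flight_density_threshold:
                    if rng.random() < cfg.jump_hazard:
                        stage = "D" if rng.random() < 0.5 else "E"
                        g_eff = (
                            GRAVITY
                            if stage == "D"
                            else rng.uniform(0.2, 0.8) * GRAVITY
                        )
                        v = np.zeros(3)
                        v[wall_axis] = -wall_sign * 0.3 * cfg.jump_speed
                        v[1 - wall_axis] = rng.normal(0.0, 0.1 * cfg.jump_speed)
                        v[2] = 0.9 * cfg.jump_speed
                        arc = {
                            "p0": pos.copy(),
                            "v": v,
                            "t0": t,
                            "g_eff": g_eff,
                            "stage": stage,
                        }
                        mode = stage
                        started_event = True
                else:
                    if rng.random() < cfg.flight_hazard:
                        flight = _FlightPath(pos, t, cfg.flight_duration, bottle, rng)
                        mode = "F"
                        started_event = True
                if not started_event:
                    if pos[2] < z_cap:
                        pos[2] = min(pos[2] + cfg.climb_speed * dt, z_cap)
                    else:
                        # near the top: creep up slowly and pace along the wall
                        pos[2] = min(pos[2] + 0.001 * dt, h - 0.02)
                        lat = 1 - wall_axis
                        half_lat = hd if wall_axis == 0 else hw
                        pos[lat] += lateral_dir * cfg.walk_speed * dt
                        if abs(pos[lat]) > half_lat - 0.01:
                            pos[lat] = np.sign(pos[lat]) * (half_lat - 0.01)
                            lateral_dir = -lateral_dir

            elif mode in ("D", "E"):
                tau = t - arc["t0"]
                p = arc["p0"] + arc["v"] * tau
                p[2] = arc["p0"][2] + arc["v"][2] * tau - 0.5 * arc["g_eff"] * tau**2
                if tau > 0 and p[2] <= eps:
                    pos = np.array(
                        [
                            np.clip(p[0], -hw + eps, hw - eps),
                            np.clip(p[1], -hd + eps, hd - eps),
                            eps,
                        ]
                    )
                    mode = "B"
                    walk_target, wall_axis, wall_sign = _pick_wall_target(
                        rng, pos, hw, hd
                    )
                    arc = None
                elif tau > 0 and p[2] >= h - eps:
                    # hit the ceiling: grab the nearest side wall near the top
                    wall_axis = 0 if abs(p[0]) / hw >= abs(p[1]) / hd else 1
                    wall_sign = 1.0 if p[wall_axis] >= 0 else -1.0
                    half = hw if wall_axis == 0 else hd
                    pos = p.copy()
                    pos[wall_axis] = wall_sign * (half - eps)
                    pos[1 - wall_axis] = np.clip(
                        pos[1 - wall_axis],
                        -(hd if wall_axis == 0 else hw) + eps,
                        (hd if wall_axis == 0 else hw) - eps,
                    )
                    pos[2] = h - 0.035
                    mode = "C"
                    lateral_dir = 1.0 if rng.random() < 0.5 else -1.0
                    arc = None
                elif tau > 0 and (abs(p[0]) >= hw - eps or abs(p[1]) >= hd - eps):
                    wall_axis = 0 if abs(p[0]) >= hw - eps else 1
                    wall_sign = 1.0 if p[wall_axis] >= 0 else -1.0
                    half = hw if wall_axis == 0 else hd
                    half_lat = hd if wall_axis == 0 else hw
                    pos = p.copy()
                    pos[wall_axis] = wall_sign * (half - eps)
                    pos[1 - wall_axis] = float(
                        np.clip(pos[1 - wall_axis], -half_lat + eps, half_lat - eps)
                    )
                    pos[2] = float(np.clip(pos[2], eps, h - 0.035))
                    mode = "C"
                    lateral_dir = 1.0 if rng.random() < 0.5 else -1.0
                    arc = None
                else:
                    pos = p

            elif mode == "F":
                tau = t - flight.t0
                if tau >= flight.total_T:
                    pos = flight.land_point.copy()
                    wall_axis = flight.land_axis
                    wall_sign = flight.land_sign
                    pos[2] = float(np.clip(pos[2], eps, z_cap))
                    mode = "C"
                    lateral_dir = 1.0 if rng.random() < 0.5 else -1.0
                    flight = None
                else:
                    pos = flight.position(tau)

            rows.append(
                (fly, i, t, pos[0], pos[1], pos[2], mode, bool(shakes[i]))
            )

    gt = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return gt


def _pick_wall_target(
    rng: np.random.Generator, pos: np.ndarray, hw: float, hd: float
) -> tuple[np.ndarray, int, float]:
    """Choose the nearest side wall and a target point on it."""
    dists = [hw - pos[0], hw + pos[0], hd - pos[1], hd + pos[1]]
    k = int(np.argmin(dists))
    axis, sign = (0, 1.0) if k == 0 else (0, -1.0) if k == 1 else (1, 1.0) if k == 2 else (1, -1.0)
    target = np.array([pos[0], pos[1]])
    half = hw if axis == 0 else hd
    half_lat = hd if axis == 0 else hw
    target[axis] = sign * (half - 0.001)
    target[1 - axis] = rng.uniform(-0.7, 0.7) * half_lat
    return target, axis, sign


def project_scene(
    gt: pd.DataFrame,
    cam_a: CameraModel,
    cam_b: CameraModel,
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render ground truth into per-camera detection tables.

    Camera A is sampled at the nominal frame clock; camera B's timestamps are
    jittered by up to 80% of ``sync_jitter_max`` per frame (so that frame
    pairing at the 10 ms tolerance always succeeds on clean data).  Gaussian
    pixel noise, independent dropout and Poisson-count uniform false positives
    are applied per camera.
    """
    rng = np.random.default_rng([cfg.seed, 1] if seed is None else seed)
    frames = gt["frame"].to_numpy()
    unique_frames = np.unique(frames)
    frame_time = dict(
        zip(gt["frame"].to_numpy(), gt["time_s"].to_numpy())
    )  # frame -> nominal time
    jitter = dict(
        zip(
            unique_frames,
            rng.uniform(-0.8, 0.8, len(unique_frames)) * cfg.sync_jitter_max,
        )
    )
    points = gt[["x_m", "y_m", "z_m"]].to_numpy()

    out = []
    for cam, is_b in ((cam_a, False), (cam_b, True)):
        pix, depth = cam.project(points)
        visible = cam.in_frame(pix, depth)
        keep = visible & (rng.random(len(pix)) >= cfg.dropout_rate)
        pix_noisy = pix[keep] + rng.normal(0.0, cfg.pixel_noise_sd, (keep.sum(), 2))
        f_keep = frames[keep]
        t_keep = np.array(
            [frame_time[f] + (jitter[f] if is_b else 0.0) for f in f_keep]
        )
        conf = rng.uniform(0.8, 1.0, keep.sum())
        det = pd.DataFrame(
            {
                "camera_id": cam.camera_id,
                "frame": f_keep,
                "time_s": t_keep,
                "x_px": pix_noisy[:, 0],
                "y_px": pix_noisy[:, 1],
                "confidence": conf,
            }
        )
        # false positives: uniform in the image, Poisson count per frame
        n_fp = rng.poisson(cfg.false_positive_rate, len(unique_frames))
        fp_frames = np.repeat(unique_frames, n_fp)
        if len(fp_frames):
            w, hgt = cam.image_size
            fp = pd.DataFrame(
                {
                    "camera_id": cam.camera_id,
                    "frame": fp_frames,
                    "time_s": [
                        frame_time[f] + (jitter[f] if is_b else 0.0)
                        for f in fp_frames
                    ],
                    "x_px": rng.uniform(0, w - 1, len(fp_frames)),
                    "y_px": rng.uniform(0, hgt - 1, len(fp_frames)),
                    "confidence": rng.uniform(0.3, 0.7, len(fp_frames)),
                }
            )
            det = pd.concat([det, fp], ignore_index=True)
        det = det.sort_values(["frame", "x_px"], kind="stable").reset_index(drop=True)
        out.append(det)
    return out[0], out[1]


def shake_table(gt: pd.DataFrame) -> pd.DataFrame:
    """Per-frame shake flags extracted from a ground-truth table."""
    return (
        gt[["frame", "time_s", "shake"]]
        .drop_duplicates("frame")
        .sort_values("frame")
        .reset_index(drop=True)
    )


def simulate_experiment(
    cfg: SimConfig,
    flush_species: str = "He",
    bottle: BottleGeometry | None = None,
    cams: tuple[CameraModel, CameraModel] | None = None,
    ambient_pO2: float = 210.0,
) -> dict:
    """Run the full generator: O2 course, ground truth, and both detection tables."""
    from .geometry import default_stereo_rig

    bottle = bottle or BottleGeometry()
    if cams is None:
        cams = default_stereo_rig(bottle)
    o2 = simulate_o2_timecourse(
        flush_species=flush_species,
        flush_duration=cfg.o2_flush_duration,
        recovery_rate=cfg.o2_recovery_rate,
        duration=cfg.duration,
        ambient_pO2=ambient_pO2,
        sample_interval=cfg.o2_sample_interval,
    )
    gt = simulate_flies(
        cfg, o2, bottle, flush_species=flush_species, ambient_pO2=ambient_pO2
    )
    det_a, det_b = project_scene(gt, cams[0], cams[1], cfg)
    return {
        "config": cfg,
        "flush_species": get_species(flush_species).name,
        "ambient_pO2": ambient_pO2,
        "bottle": bottle,
        "cameras": cams,
        "o2": o2,
        "ground_truth": gt,
        "detections_a": det_a,
        "detections_b": det_b,
        "shake": shake_table(gt),
    }
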