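"""End-to-end experiment driver.

Joins behavior events with the O2 sensor series, converts each event's pO2
to a mixture density, and summarizes each run the way the assay reports its
results: the minimal pO2 (and the corresponding density) at which activity,
climbing, and flight were first documented.  Thresholds are computed over the
recovery phase only — events recorded before the pO2 minimum of the run
(i.e. during the flush itself, when ambient air is still present) are
excluded from the minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import classify_tracks
from .gas import GasState, get_species, mixture_density
from .geometry import BottleGeometry, CameraModel, default_stereo_rig
from .simulate import O2Series, SimConfig, simulate_experiment
from .stereo import reconstruct
from .tracking import two_pass_link

logger = logging.getLogger("flydense")

#: Stages counting as "active" for the first-activity threshold.
ACTIVE_STAGES = ("B", "C", "D", "E", "F")

SUMMARY_COLUMNS = [
    "experiment",
    "gas",
    "first_activity_pO2",
    "first_activity_density",
    "first_climbing_pO2",
    "first_climbing_density",
    "first_flight_pO2",
    "first_flight_density",
]


def attach_pO2(
    events: pd.DataFrame,
    o2: O2Series,
    flush_species: str,
    ambient_pO2: float = 210.0,
    ref_temperature: float = 273.15,
    ref_pressure: float = 1013.25,
) -> pd.DataFrame:
    """Interpolate pO2 at each event's start time and attach the mixture density.

    Raises if any event starts outside the sensor-series time span.
    """
    out = events.copy()
    if out.empty:
        out["pO2_mbar"] = pd.Series(dtype=float)
        out["density_kg_m3"] = pd.Series(dtype=float)
        return out
    t0, t1 = o2.span
    ts = out["t_start"].to_numpy(dtype=float)
    if ts.min() < t0 - 1e-9 or ts.max() > t1 + 1e-9:
        raise ValueError(
            f"event times [{ts.min():.3f}, {ts.max():.3f}] s outside the O2 "
            f"series span [{t0:.3f}, {t1:.3f}] s"
        )
    species = get_species(flush_species)
    po2 = o2.interp(ts)
    out["pO2_mbar"] = po2
    out["density_kg_m3"] = [
        mixture_density(
            GasState(
                species,
                min(p, ambient_pO2),
                ambient_pO2=ambient_pO2,
                ref_temperature=ref_temperature,
                ref_pressure=ref_pressure,
            )
        )
        for p in po2
    ]
    return out


def _first_occurrence(
    sub: pd.DataFrame, corroboration: int, window_s: float
) -> pd.Series | None:
    """Earliest qualifying event, optionally requiring corroboration.

    With ``corroboration`` > 1 the first event must be followed by at least
    ``corroboration`` - 1 further qualifying events within ``window_s``
    seconds; isolated events (reconstruction artifacts) are skipped.  This is
    the automated stand-in for manually vetting the first clear behavior of
    each kind.
    """
    if sub.empty:
        return None
    sub = sub.sort_values("t_start")
    times = sub["t_start"].to_numpy()
    for i in range(len(sub)):
        n_close = int(np.sum((times >= times[i]) & (times <= times[i] + window_s)))
        if n_close >= corroboration:
            cluster = sub[(times >= times[i]) & (times <= times[i] + window_s)]
            return cluster.loc[cluster["pO2_mbar"].idxmin()]
    return None


def first_occurrence_table(
    events: pd.DataFrame,
    aggregate: str = "per_experiment",
    corroboration: int = 1,
    window_s: float = 15.0,
) -> pd.DataFrame:
    """Minimal pO2 (and density) of first activity, climbing and flight.

    ``events`` must carry ``experiment``, ``gas``, ``stage``, ``pO2_mbar`` and
    ``density_kg_m3`` columns.  Activity is any stage B or higher, climbing is
    stage C, flight is stage F.  With ``aggregate='per_gas'`` the minima are
    taken over replicates of the same gas.  Missing behaviors yield NaN, not
    zero.  ``corroboration`` > 1 requires each reported onset to be backed by
    that many events within ``window_s`` seconds (see
    :func:`_first_occurrence`); the default reproduces the plain minimum.
    """
    if events.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    rows = []
    for (exp, gas), grp in events.groupby(["experiment", "gas"]):
        row = {"experiment": exp, "gas": gas}
        for label, mask in (
            ("first_activity", grp["stage"].isin(ACTIVE_STAGES)),
            ("first_climbing", grp["stage"] == "C"),
            ("first_flight", grp["stage"] == "F"),
        ):
            best = _first_occurrence(grp[mask], corroboration, window_s)
            if best is None:
                row[f"{label}_pO2"] = np.nan
                row[f"{label}_density"] = np.nan
            else:
                row[f"{label}_pO2"] = float(best["pO2_mbar"])
                row[f"{label}_density"] = float(best["density_kg_m3"])
        rows.append(row)
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if aggregate == "per_gas":
        agg_rows = []
        for gas, grp in out.groupby("gas"):
            row = {"experiment": "all", "gas": gas}
            for col in SUMMARY_COLUMNS[2:]:
                vals = grp[col].dropna()
                row[col] = float(vals.min()) if len(vals) else np.nan
            agg_rows.append(row)
        out = pd.DataFrame(agg_rows, columns=SUMMARY_COLUMNS)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one simulated run through the full pipeline."""

    flush_species: str = "He"
    experiment: str = "run_1"
    sim: SimConfig = field(default_factory=SimConfig)
    ambient_pO2: float = 210.0
    error_threshold_px: float = 3.0
    max_dt: float = 0.010
    recovery_phase_only: bool = True
    corroboration: int = 3
    corroboration_window_s: float = 15.0


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(
    config: PipelineConfig,
    bottle: BottleGeometry | None = None,
    cams: tuple[CameraModel, CameraModel] | None = None,
) -> dict:
    """simulate -> reconstruct -> track -> classify -> attach pO2 -> summarize.

    Returns a dict with every intermediate artifact plus the summary table.
    """
    bottle = bottle or BottleGeometry()
    if cams is None:
        cams = default_stereo_rig(bottle)
    artifacts: dict = {}

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        artifacts[name] = result
        return result

    logger.info(
        "pipeline start: gas=%s seed=%d duration=%.0fs",
        config.flush_species,
        config.sim.seed,
        config.sim.duration,
    )
    sim = _stage(
        "simulate",
        lambda: simulate_experiment(
            config.sim,
            flush_species=config.flush_species,
            bottle=bottle,
            cams=cams,
            ambient_pO2=config.ambient_pO2,
        ),
    )
    points = _stage(
        "reconstruct",
        lambda: reconstruct(
            sim["detections_a"],
            sim["detections_b"],
            cams[0],
            cams[1],
            shake_flags=sim["shake"],
            max_dt=config.max_dt,
            error_threshold_px=config.error_threshold_px,
            bottle=bottle,
        ),
    )
    logger.info("reconstructed %d points", len(points))
    tracks = _stage(
        "track",
        lambda: two_pass_link(points[["frame", "time_s", "x_m", "y_m", "z_m"]]),
    )
    events = _stage(
        "classify",
        lambda: classify_tracks(
            tracks, bottle, body_length=config.sim.body_length
        ),
    )
    logger.info(
        "events per stage: %s",
        events["stage"].value_counts().to_dict() if len(events) else {},
    )
    events = _stage(
        "attach_pO2",
        lambda: attach_pO2(
            events, sim["o2"], config.flush_species, ambient_pO2=config.ambient_pO2
        ),
    )
    events = events.copy()
    events["experiment"] = config.experiment
    events["gas"] = get_species(config.flush_species).name
    artifacts["events"] = events

    if config.recovery_phase_only and len(events):
        t_min = float(sim["o2"].times[int(np.argmin(sim["o2"].po2))])
        scored = events[events["t_start"] >= t_min]
    else:
        scored = events
    summary = _stage(
        "summarize",
        lambda: first_occurrence_table(
            scored,
            corroboration=config.corroboration,
            window_s=config.corroboration_window_s,
        ),
    )
    artifacts["summary"] = summary
    artifacts["tracks"] = tracks
    artifacts["points"] = points
    return artifacts
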