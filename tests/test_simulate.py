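"""Synthetic-assay generator: O2 course, fly behavior, camera projection."""

import math

import numpy as np
import pandas as pd
import pytest

from flydense.gas import mixture_density_for
from flydense.simulate import (
    DEFAULT_RECOVERY_RATES,
    GRAVITY,
    O2Series,
    SimConfig,
    o2_recovery_time,
    project_scene,
    simulate_experiment,
    simulate_flies,
    simulate_o2_timecourse,
)


class TestO2Timecourse:
    def test_starts_at_ambient(self):
        o2 = simulate_o2_timecourse("He")
        assert o2.po2[0] == pytest.approx(210.0)

    def test_flush_reaches_near_zero_then_monotone_recovery(self):
        o2 = simulate_o2_timecourse("He", flush_duration=20.0, duration=300.0)
        after = o2.po2[o2.times > 20.0]
        assert o2.po2[o2.times <= 20.0].min() < 2.0
        assert np.all(np.diff(after) >= -1e-12)

    def test_relaxes_to_ambient_within_one_percent(self):
        o2 = simulate_o2_timecourse("He", duration=600.0)
        assert o2.po2[-1] > 0.99 * 210.0

    def test_helium_reaches_142_mbar_before_nitrogen(self):
        t_he = o2_recovery_time(142.0, DEFAULT_RECOVERY_RATES["He"])
        t_n2 = o2_recovery_time(142.0, DEFAULT_RECOVERY_RATES["N2"])
        assert t_he < t_n2
        # the sampled series crosses at the closed-form time
        o2 = simulate_o2_timecourse("He", duration=400.0)
        crossing = o2.times[np.searchsorted(o2.po2, 142.0)]
        assert abs(crossing - t_he) <= 1.5  # within sampling resolution

    def test_series_matches_closed_form(self):
        o2 = simulate_o2_timecourse("N2", flush_duration=20.0, duration=200.0)
        k = DEFAULT_RECOVERY_RATES["N2"]
        mask = o2.times > 20.0
        expected = 210.0 - 209.0 * np.exp(-k * (o2.times[mask] - 20.0))
        assert np.allclose(o2.po2[mask], expected, atol=1e-9)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            simulate_o2_timecourse("He", duration=-5.0)


class TestSimulateFlies:
    def test_deterministic_under_fixed_seed(self, bottle):
        cfg = SimConfig(seed=7, duration=30.0, n_flies=3)
        o2 = simulate_o2_timecourse("He", duration=30.0)
        gt1 = simulate_flies(cfg, o2, bottle, "He")
        gt2 = simulate_flies(cfg, o2, bottle, "He")
        pd.testing.assert_frame_equal(gt1, gt2)

    def test_hypoxic_flies_are_immobile(self, bottle):
        cfg = SimConfig(seed=2, duration=20.0, n_flies=3)
        o2 = O2Series(np.array([0.0, 20.0]), np.array([5.0, 5.0]))
        gt = simulate_flies(cfg, o2, bottle, "He")
        assert (gt["stage"] == "A").all()
        disp = gt.groupby("fly_id")[["x_m", "y_m", "z_m"]].agg(lambda s: s.max() - s.min())
        assert (disp.to_numpy() == 0).all()

    def test_positions_stay_inside_bottle(self, noiseless_he_ground_truth, bottle):
        _, gt = noiseless_he_ground_truth
        assert bottle.contains(gt[["x_m", "y_m", "z_m"]].to_numpy()).all()

    def test_ballistic_stages_are_exact_parabolas(self, noiseless_he_ground_truth):
        _, gt = noiseless_he_ground_truth
        found = 0
        for fly, grp in gt.groupby("fly_id"):
            stages = grp["stage"].to_numpy()
            start = None
            for i in range(len(stages)):
                if stages[i] in "DE" and start is None:
                    start = i
                elif stages[i] not in "DE" and start is not None:
                    seg = grp.iloc[start:i]
                    if len(seg) >= 5:
                        t = seg["time_s"].to_numpy()
                        coef = np.polyfit(t - t[0], seg["z_m"].to_numpy(), 2)
                        resid = seg["z_m"].to_numpy() - np.polyval(coef, t - t[0])
                        g_eff = -2.0 * coef[0]
                        assert np.abs(resid).max() < 1e-9
                        if seg["stage"].iat[0] == "D":
                            assert g_eff == pytest.approx(GRAVITY, abs=0.01)
                        else:
                            assert 0.2 * GRAVITY <= g_eff <= 0.8 * GRAVITY
                        found += 1
                    start = None
        assert found > 5

    def test_flight_deviates_from_parabola_but_jumps_do_not(
        self, noiseless_he_ground_truth
    ):
        _, gt = noiseless_he_ground_truth
        checked = 0
        for fly, grp in gt.groupby("fly_id"):
            stages = grp["stage"].to_numpy()
            start = None
            for i in range(len(stages) + 1):
                here = stages[i] if i < len(stages) else "-"
                if here == "F" and start is None:
                    start = i
                elif here != "F" and start is not None:
                    seg = grp.iloc[start + 2 : i - 2]  # interior of the flight
                    start = None
                    if len(seg) < 30:
                        continue
                    t = seg["time_s"].to_numpy()
                    p = seg[["x_m", "y_m", "z_m"]].to_numpy()
                    res = []
                    for axis, deg in ((0, 1), (1, 1), (2, 2)):
                        c = np.polyfit(t - t[0], p[:, axis], deg)
                        res.append(p[:, axis] - np.polyval(c, t - t[0]))
                    rms = float(np.sqrt(np.mean(np.concatenate(res) ** 2)))
                    extent = float(np.ptp(p[:, 2]))
                    assert rms > 0.15 * extent or rms > 0.003
                    checked += 1
        assert checked > 3

    def test_first_flight_frame_tracks_density_gate(self, noiseless_he_ground_truth):
        o2, gt = noiseless_he_ground_truth
        gate_po2 = 142.0  # mixture density 0.93 at this pO2 under He flush
        assert round(mixture_density_for("He", gate_po2), 2) == 0.93
        crossing = float(o2.times[np.searchsorted(o2.po2, gate_po2)])
        f_times = gt.loc[gt["stage"] == "F", "time_s"]
        assert f_times.min() >= crossing - 1.5
        assert f_times.min() <= crossing + 5.0

    def test_nitrogen_runs_skip_jump_stages(self, clean_sim_config, bottle):
        o2 = simulate_o2_timecourse("N2", duration=clean_sim_config.duration)
        gt = simulate_flies(clean_sim_config, o2, bottle, "N2")
        assert not gt["stage"].isin(["D", "E"]).any()
        assert (gt["stage"] == "F").any()

    def test_helium_runs_have_jump_stages(self, noiseless_he_ground_truth):
        _, gt = noiseless_he_ground_truth
        assert gt["stage"].isin(["D"]).any()
        assert gt["stage"].isin(["E"]).any()

    def test_shake_flags_follow_schedule(self, noiseless_he_ground_truth, clean_sim_config):
        _, gt = noiseless_he_ground_truth
        one_fly = gt[gt["fly_id"] == 0]
        expected = (
            one_fly["time_s"].to_numpy() % clean_sim_config.shake_period
        ) < clean_sim_config.shake_duration
        assert (one_fly["shake"].to_numpy() == expected).all()


class TestProjectScene:
    def _single_fly_gt(self, n=50):
        return pd.DataFrame(
            {
                "fly_id": 0,
                "frame": np.arange(n),
                "time_s": np.arange(n) / 30.0,
                "x_m": 0.01,
                "y_m": -0.005,
                "z_m": 0.1,
                "stage": "A",
                "shake": False,
            }
        )

    def test_noiseless_projection_is_exact(self, rig):
        cam_a, cam_b = rig
        cfg = SimConfig(
            seed=0, pixel_noise_sd=0.0, dropout_rate=0.0, false_positive_rate=0.0
        )
        gt = self._single_fly_gt()
        det_a, det_b = project_scene(gt, cam_a, cam_b, cfg)
        assert len(det_a) == len(gt) and len(det_b) == len(gt)
        ideal, _ = cam_a.project(np.array([[0.01, -0.005, 0.1]]))
        assert np.allclose(det_a[["x_px", "y_px"]].to_numpy(), ideal[0], atol=1e-9)

    def test_full_dropout_empties_tables(self, rig):
        cfg = SimConfig(seed=0, dropout_rate=1.0, false_positive_rate=0.0)
        det_a, det_b = project_scene(self._single_fly_gt(), rig[0], rig[1], cfg)
        assert det_a.empty and det_b.empty

    def test_pixel_noise_has_rayleigh_mean_offset(self, rig):
        cam_a, _ = rig
        cfg = SimConfig(
            seed=3, pixel_noise_sd=1.0, dropout_rate=0.0, false_positive_rate=0.0
        )
        gt = self._single_fly_gt(n=12000)
        det_a, _ = project_scene(gt, cam_a, rig[1], cfg)
        ideal, _ = cam_a.project(np.array([[0.01, -0.005, 0.1]]))
        offsets = np.linalg.norm(det_a[["x_px", "y_px"]].to_numpy() - ideal[0], axis=1)
        assert offsets.mean() == pytest.approx(math.sqrt(math.pi / 2), abs=0.05)

    def test_timestamps_stay_within_sync_jitter(self, rig):
        cfg = SimConfig(seed=1, dropout_rate=0.0, false_positive_rate=0.0)
        gt = self._single_fly_gt()
        det_a, det_b = project_scene(gt, rig[0], rig[1], cfg)
        merged = det_a.merge(det_b, on="frame", suffixes=("_a", "_b"))
        dt = (merged["time_s_b"] - merged["time_s_a"]).abs()
        assert (dt <= cfg.sync_jitter_max).all()

    def test_simulate_experiment_is_deterministic(self):
        cfg = SimConfig(seed=11, duration=15.0, n_flies=2)
        a = simulate_experiment(cfg, flush_species="He")
        b = simulate_experiment(cfg, flush_species="He")
        pd.testing.assert_frame_equal(a["detections_a"], b["detections_a"])
        pd.testing.assert_frame_equal(a["ground_truth"], b["ground_truth"])
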