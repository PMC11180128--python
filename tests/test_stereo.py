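"""Frame pairing, triangulation and exhaustive stereo matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from flydense.geometry import BottleGeometry, CameraModel, default_stereo_rig
from flydense.stereo import (
    DegenerateGeometryError,
    match_all_pairs,
    min_cost_match,
    pair_frames,
    reconstruct,
    reject_shake_frames,
    triangulate,
)


def _det_table(times, camera_id="cam"):
    return pd.DataFrame(
        {
            "camera_id": camera_id,
            "frame": np.arange(len(times)),
            "time_s": times,
            "x_px": 100.0,
            "y_px": 100.0,
            "confidence": 1.0,
        }
    )


class TestPairFrames:
    def test_identical_timestamps_pair_everything(self):
        t = np.arange(20) / 30.0
        pairs = pair_frames(_det_table(t), _det_table(t))
        assert len(pairs) == 20
        assert np.allclose(pairs["dt"], 0.0)

    def test_offset_beyond_tolerance_pairs_nothing(self):
        t = np.arange(20) / 30.0
        pairs = pair_frames(_det_table(t), _det_table(t + 0.020), max_dt=0.010)
        assert pairs.empty

    def test_seven_ms_offset_pairs_all_with_correct_dt(self):
        t = np.arange(20) / 30.0
        pairs = pair_frames(_det_table(t), _det_table(t + 0.007), max_dt=0.010)
        # brute-force nearest-neighbor oracle
        for ta in t:
            assert np.min(np.abs((t + 0.007) - ta)) == pytest.approx(0.007)
        assert len(pairs) == 20
        assert np.allclose(pairs["dt"], 0.007)

    def test_pairs_are_disjoint(self, rng):
        ta = np.sort(rng.uniform(0, 1, 40))
        tb = np.sort(rng.uniform(0, 1, 40))
        pairs = pair_frames(_det_table(ta), _det_table(tb), max_dt=0.05)
        assert pairs["frame_a"].is_unique
        assert pairs["frame_b"].is_unique


class TestRejectShake:
    def _pairs(self, n):
        t = np.arange(n) / 30.0
        return pair_frames(_det_table(t), _det_table(t))

    def test_no_flags_is_identity(self):
        pairs = self._pairs(10)
        flags = pd.DataFrame({"frame": np.arange(10), "shake": False})
        assert len(reject_shake_frames(pairs, flags)) == 10

    def test_all_flagged_empties(self):
        pairs = self._pairs(10)
        flags = pd.DataFrame({"frame": np.arange(10), "shake": True})
        assert reject_shake_frames(pairs, flags).empty

    def test_alternating_flags_keep_half(self):
        pairs = self._pairs(10)
        flags = pd.DataFrame({"frame": np.arange(10), "shake": [True, False] * 5})
        out = reject_shake_frames(pairs, flags)
        assert len(out) == 5
        assert set(out["frame_a"]) == {1, 3, 5, 7, 9}

    def test_missing_flags_is_an_error(self):
        pairs = self._pairs(10)
        flags = pd.DataFrame({"frame": np.arange(5), "shake": False})
        with pytest.raises(ValueError, match="missing"):
            reject_shake_frames(pairs, flags)


class TestTriangulate:
    def test_exact_inversion_of_projection(self, rig, rng):
        cam_a, cam_b = rig
        for _ in range(20):
            point = np.array(
                [rng.uniform(-0.04, 0.04), rng.uniform(-0.02, 0.02), rng.uniform(0.02, 0.2)]
            )
            pa, _ = cam_a.project(point)
            pb, _ = cam_b.project(point)
            rec, err = triangulate(pa[0], pb[0], cam_a, cam_b)
            assert np.linalg.norm(rec - point) < 1e-6
            assert err < 1e-6

    def test_noise_gives_sub_mm_3d_error(self, rng):
        # 0.3 m baseline, 90 degree vergence, 1000 px focal, 1 px noise
        target = np.array([0.0, 0.0, 0.1])
        d = 0.3 / np.sqrt(2)
        cam_a = CameraModel.look_at("a", [d, 0.0, 0.1], target, focal_px=1000.0)
        cam_b = CameraModel.look_at("b", [0.0, -d, 0.1], target, focal_px=1000.0)
        errors = []
        for _ in range(400):
            point = target + rng.uniform(-0.02, 0.02, 3)
            pa, _ = cam_a.project(point)
            pb, _ = cam_b.project(point)
            rec, _ = triangulate(
                pa[0] + rng.normal(0, 1, 2), pb[0] + rng.normal(0, 1, 2), cam_a, cam_b
            )
            errors.append(np.linalg.norm(rec - point))
        med = np.median(errors)
        assert 3e-5 < med < 1e-3  # of order 1e-4 m

    def test_cross_fly_pairs_have_large_error(self, rig):
        cam_a, cam_b = rig
        flies = np.array([[0.0, 0.0, 0.05], [0.02, 0.01, 0.12], [-0.03, -0.02, 0.19]])
        pa, _ = cam_a.project(flies)
        pb, _ = cam_b.project(flies)
        for i, j in itertools.permutations(range(3), 2):
            _, err = triangulate(pa[i], pb[j], cam_a, cam_b)
            assert err > 3.0  # flies separated well away from epipolar coincidence

    def test_parallel_rays_are_degenerate(self):
        cam_a = CameraModel.look_at("a", [0.5, 0.0, 0.1], [0.0, 0.0, 0.1])
        cam_b = CameraModel(
            "b",
            cam_a.focal_px,
            cam_a.principal_point,
            cam_a.image_size,
            cam_a.rotation,
            cam_a.rotation @ -np.array([0.5, 0.05, 0.1]),
        )
        with pytest.raises(DegenerateGeometryError):
            triangulate(np.array([960.0, 540.0]), np.array([960.0, 540.0]), cam_a, cam_b)


class TestMatchAllPairs:
    def test_three_flies_recovered_and_match_brute_force(self, rig):
        cam_a, cam_b = rig
        flies = np.array([[0.0, 0.0, 0.05], [0.02, 0.01, 0.12], [-0.03, -0.02, 0.19]])
        pa, _ = cam_a.project(flies)
        pb, _ = cam_b.project(flies)
        out = match_all_pairs(pa, pb, cam_a, cam_b, error_threshold_px=3.0)
        assert len(out) == 3
        rec = out.sort_values("det_a")[["x_m", "y_m", "z_m"]].to_numpy()
        assert np.allclose(rec, flies, atol=1e-6)
        # brute-force oracle over all 9 candidates / 6 one-to-one matchings
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(3)):
            cost = 0.0
            for i, j in enumerate(perm):
                _, err = triangulate(pa[i], pb[j], cam_a, cam_b)
                cost += err
            if cost < best_cost:
                best, best_cost = perm, cost
        assert best == (0, 1, 2)

    def test_empty_camera_gives_empty_output(self, rig):
        cam_a, cam_b = rig
        out = match_all_pairs(np.empty((0, 2)), np.array([[100.0, 100.0]]), cam_a, cam_b)
        assert out.empty

    def test_epipolar_coincident_flies_resolved_one_to_one(self, rig):
        # both flies in the plane through the two camera centers: all four
        # candidate pairs triangulate exactly, greedy keeps two
        cam_a, cam_b = rig
        z = cam_a.center[2]  # camera centers share this height
        flies = np.array([[0.01, 0.0, z], [-0.01, -0.02, z]])
        pa, _ = cam_a.project(flies)
        pb, _ = cam_b.project(flies)
        from flydense.stereo import _pairwise_triangulate

        _, err, _ = _pairwise_triangulate(pa, pb, cam_a, cam_b)
        assert (err <= 3.0).sum() == 4
        out = match_all_pairs(pa, pb, cam_a, cam_b, error_threshold_px=3.0)
        assert len(out) == 2
        assert out["det_a"].is_unique and out["det_b"].is_unique

    def test_greedy_matches_optimal_on_random_scenes(self, rig, rng):
        cam_a, cam_b = rig
        agree = 0
        n_scenes = 100
        for _ in range(n_scenes):
            n = rng.integers(1, 6)
            flies = np.column_stack(
                [
                    rng.uniform(-0.045, 0.045, n),
                    rng.uniform(-0.028, 0.028, n),
                    rng.uniform(0.01, 0.22, n),
                ]
            )
            pa, _ = cam_a.project(flies)
            pb, _ = cam_b.project(flies)
            g = match_all_pairs(pa, pb, cam_a, cam_b)
            o = min_cost_match(pa, pb, cam_a, cam_b)
            if set(zip(g["det_a"], g["det_b"])) == set(zip(o["det_a"], o["det_b"])):
                agree += 1
        assert agree >= 0.95 * n_scenes


class TestReconstruct:
    def test_noiseless_points_inside_dilated_bottle(self, rig, bottle, rng):
        cam_a, cam_b = rig
        n_frames, n_flies = 40, 3
        rows_a, rows_b, truth = [], [], []
        for f in range(n_frames):
            flies = np.column_stack(
                [
                    rng.uniform(-0.04, 0.04, n_flies),
                    rng.uniform(-0.025, 0.025, n_flies),
                    rng.uniform(0.01, 0.2, n_flies),
                ]
            )
            truth.append(flies)
            pa, _ = cam_a.project(flies)
            pb, _ = cam_b.project(flies)
            for k in range(n_flies):
                rows_a.append(("cam_a", f, f / 30.0, pa[k, 0], pa[k, 1], 1.0))
                rows_b.append(("cam_b", f, f / 30.0, pb[k, 0], pb[k, 1], 1.0))
        cols = ["camera_id", "frame", "time_s", "x_px", "y_px", "confidence"]
        det_a = pd.DataFrame(rows_a, columns=cols)
        det_b = pd.DataFrame(rows_b, columns=cols)
        points = reconstruct(det_a, det_b, cam_a, cam_b)
        assert len(points) == n_frames * n_flies
        assert bottle.contains(
            points[["x_m", "y_m", "z_m"]].to_numpy(), dilation=0.01
        ).all()
        # one-to-one: no detection is reused
        assert points.groupby("frame")["det_a"].nunique().eq(n_flies).all()


class TestCalibrationIO:
    def test_yaml_round_trip(self, rig, bottle, tmp_path):
        from flydense import io

        path = io.save_calibration(tmp_path / "rig.yaml", bottle, rig)
        bottle2, cams = io.load_calibration(path)
        assert bottle2 == bottle
        assert np.allclose(cams[0].rotation, rig[0].rotation)
        assert np.allclose(cams[1].translation, rig[1].translation)
        assert cams[0].camera_id == "cam_a"
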