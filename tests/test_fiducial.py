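"""Cube projection, pose estimation, and two-cube tracking."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from echoguide.fiducial import (
    CornerDetections,
    CubeModel,
    PinholeCamera,
    estimate_pose,
    project_cube,
    reprojection_rms,
    track_frame,
)
from echoguide.geometry import Pose, compose, pose_error, relative_pose

CAM = PinholeCamera(fx=800, fy=800, cx=320, cy=240, width=640, height=480)
CUBE = CubeModel(40.0)


def random_visible_pose(rng, z_range=(400.0, 600.0), xy_mm=60.0):
    """Random cube pose with all 8 corners inside the image."""
    while True:
        rot = Rotation.random(rng=rng)
        t = np.array(
            [rng.uniform(-xy_mm, xy_mm), rng.uniform(-xy_mm, xy_mm), rng.uniform(*z_range)]
        )
        pose = Pose.from_rotation(rot, t, "camera", "cube")
        det = project_cube(CAM, pose, CUBE)
        if det.n_visible == 8:
            return pose


class TestCubeModel:
    def test_corner_distances_match_edge_face_space_diagonals(self):
        c = CUBE.corners
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        vals = np.unique(np.round(d[d > 0], 9))
        e = 40.0
        assert np.allclose(vals, [e, e * np.sqrt(2), e * np.sqrt(3)])

    def test_positive_edge_required(self):
        with pytest.raises(ValueError):
            CubeModel(0.0)


class TestProjectCube:
    def test_pinhole_formula(self):
        # corner (+20,+20,+20) of a cube at (0,0,500): u = cx + fx*20/520
        pose = Pose(np.array([1.0, 0, 0, 0]), (0, 0, 500), "camera", "cube")
        det = project_cube(CAM, pose, CUBE)
        corner_idx = 7  # (+,+,+) in sign-bit order
        assert np.allclose(
            det.uv[corner_idx], (320 + 800 * 20 / 520, 240 + 800 * 20 / 520), atol=1e-9
        )

    def test_on_axis_cube_projects_symmetrically(self):
        pose = Pose(np.array([1.0, 0, 0, 0]), (0, 0, 500), "camera", "cube")
        det = project_cube(CAM, pose, CUBE)
        centered = det.uv - (CAM.cx, CAM.cy)
        assert np.allclose(sorted(centered[:, 0]), sorted(-centered[:, 0]), atol=1e-9)

    def test_cube_behind_camera_is_an_error(self):
        pose = Pose(np.array([1.0, 0, 0, 0]), (0, 0, -500), "camera", "cube")
        with pytest.raises(ValueError, match="front of the camera"):
            project_cube(CAM, pose, CUBE)

    def test_noise_is_reproducible_per_seed(self):
        pose = Pose(np.array([1.0, 0, 0, 0]), (0, 0, 500), "camera", "cube")
        a = project_cube(CAM, pose, CUBE, 0.5, rng=42)
        b = project_cube(CAM, pose, CUBE, 0.5, rng=42)
        assert np.array_equal(a.uv, b.uv)


class TestEstimatePose:
    def test_noiseless_round_trip_recovers_generating_pose(self, rng):
        for _ in range(50):
            pose = random_visible_pose(rng)
            est, rms = estimate_pose(CAM, CUBE, project_cube(CAM, pose, CUBE))
            err = pose_error(pose, est)
            assert err.translation_mm < 1e-6 and err.rotation_deg < 1e-6
            assert rms < 1e-6

    def test_three_corners_is_untrackable(self):
        pose = Pose(np.array([1.0, 0, 0, 0]), (0, 0, 500), "camera", "cube")
        det = project_cube(CAM, pose, CUBE)
        det.visible[3:] = False
        est, rms = estimate_pose(CAM, CUBE, det)
        assert est is None and np.isnan(rms)

    def test_four_corners_suffice(self, rng):
        pose = random_visible_pose(rng)
        det = project_cube(CAM, pose, CUBE)
        keep = np.zeros(8, bool)
        keep[[0, 3, 5, 6]] = True  # tetrahedral, non-coplanar subset
        det.visible &= keep
        est, _ = estimate_pose(CAM, CUBE, det)
        err = pose_error(pose, est)
        assert err.translation_mm < 1e-5 and err.rotation_deg < 1e-5

    def test_estimator_matches_truth_initialized_oracle_under_noise(self, rng):
        """Medians over random poses vs refinement started at the true pose."""
        n = 120
        ours, oracle = [], []
        for _ in range(n):
            pose = random_visible_pose(rng)
            det = project_cube(CAM, pose, CUBE, noise_sigma_px=0.5, rng=rng)
            if det.n_visible < 4:
                continue
            est, _ = estimate_pose(CAM, CUBE, det)
            ours.append(pose_error(pose, est))

            vis = det.visible
            obj, uv = CUBE.corners[vis], det.uv[vis]

            def resid(params):
                pts = Rotation.from_rotvec(params[:3]).apply(obj) + params[3:]
                pred = np.column_stack(
                    (CAM.cx + CAM.fx * pts[:, 0] / pts[:, 2], CAM.cy + CAM.fy * pts[:, 1] / pts[:, 2])
                )
                return (pred - uv).ravel()

            x0 = np.concatenate([pose.rotation.as_rotvec(), pose.t])
            sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
            ref = Pose.from_rotation(Rotation.from_rotvec(sol.x[:3]), sol.x[3:], "camera", "cube")
            oracle.append(pose_error(pose, ref))

        med = lambda errs, attr: float(np.median([getattr(e, attr) for e in errs]))
        for attr in ("translation_mm", "rotation_deg"):
            a, b = med(ours, attr), med(oracle, attr)
            assert abs(a - b) <= 0.1 * max(a, b), (attr, a, b)

    def test_reported_rms_not_worse_than_ground_truth_pose(self, rng):
        for _ in range(30):
            pose = random_visible_pose(rng)
            det = project_cube(CAM, pose, CUBE, noise_sigma_px=1.0, rng=rng)
            if det.n_visible < 4:
                continue
            est, rms = estimate_pose(CAM, CUBE, det)
            assert rms <= reprojection_rms(CAM, CUBE, pose, det) + 1e-9

    def test_error_degrades_gracefully_with_noise(self, rng):
        """Median pose error is non-decreasing in the corner-noise sigma."""
        sigmas = [0.0, 0.25, 0.5, 1.0]
        medians = []
        poses = [random_visible_pose(rng) for _ in range(200)]
        for sigma in sigmas:
            errs = []
            for pose in poses:
                det = project_cube(CAM, pose, CUBE, sigma, rng=rng)
                if det.n_visible < 4:
                    continue
                est, _ = estimate_pose(CAM, CUBE, det)
                if est is not None:
                    errs.append(pose_error(pose, est).translation_mm)
            medians.append(float(np.median(errs)))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:])), medians


class TestTrackFrame:
    def _scene(self):
        ref = Pose(np.array([1.0, 0, 0, 0]), (-60, 0, 500), "camera", "reference_cube")
        probe = Pose.from_axis_angle((0, 1, 0), 15, (70, 10, 520), "camera", "probe_cube")
        return ref, probe

    def test_noiseless_relative_pose_matches_ground_truth(self):
        ref, probe = self._scene()
        status, rel = track_frame(CAM, ref, probe, CUBE, noise_sigma_px=0.0, rng=0)
        assert status.both_tracked
        err = pose_error(relative_pose(ref, probe), rel)
        assert err.translation_mm < 1e-6 and err.rotation_deg < 1e-6

    def test_probe_behind_camera_reports_untracked(self):
        ref, _ = self._scene()
        behind = Pose(np.array([1.0, 0, 0, 0]), (0, 0, -500), "camera", "probe_cube")
        status, rel = track_frame(CAM, ref, behind, CUBE, 0.0, rng=0)
        assert status.reference_tracked and not status.probe_tracked
        assert rel is None

    def test_relative_error_insensitive_to_camera_placement(self, rng):
        """Median relative-pose error under noise ~equal for two camera placements."""
        ref, probe = self._scene()
        motion = Pose.from_axis_angle((0, 1, 0), 8, (-50, 25, 60), "camera", "camera")
        truth = relative_pose(ref, probe)
        med = {}
        for name, (r, p) in {
            "A": (ref, probe),
            "B": (compose(motion, ref), compose(motion, probe)),
        }.items():
            errs = []
            for _ in range(200):
                status, rel = track_frame(CAM, r, p, CUBE, 0.5, rng=rng)
                if rel is not None:
                    errs.append(pose_error(truth, rel).translation_mm)
            med[name] = float(np.median(errs))
        assert abs(med["A"] - med["B"]) < 0.2 * max(med.values()), med


def test_detections_json_round_trip(rng):
    pose = random_visible_pose(rng)
    det = project_cube(CAM, pose, CUBE, 0.5, rng=rng)
    det2 = CornerDetections.from_json(det.to_json())
    assert np.allclose(det.uv[det.visible], det2.uv[det2.visible])
    assert np.array_equal(det.visible, det2.visible)
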