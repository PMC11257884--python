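"""Cube-fiducial tracking: pinhole projection, pose estimation, two-cube relative pose.

Functional stand-in for a commercial multi-target tracker.  The real system
tracks textured cube faces; here the correspondence primitives are the eight
cube corners, which give the same 6-DOF pose observability at desk scale
without image processing.  The solver is a homogeneous linear (DLT-style)
initialization followed by Levenberg-Marquardt refinement of the reprojection
error; there is no RANSAC because the simulation produces no outliers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import Pose, relative_pose

__all__ = [
    "CubeModel",
    "PinholeCamera",
    "CornerDetections",
    "TrackingStatus",
    "project_cube",
    "estimate_pose",
    "reprojection_rms",
    "track_frame",
]

MIN_CORNERS_FOR_POSE = 4


@dataclass(frozen=True)
class CubeModel:
    """Cube fiducial; corners in the cube frame (center at origin, faces axis-aligned)."""

    edge_length_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.edge_length_mm <= 0:
            raise ValueError("edge_length_mm must be > 0")

    @property
    def corners(self) -> np.ndarray:
        """(8, 3) corner coordinates, ordered by sign bits of (x, y, z)."""
        h = self.edge_length_mm / 2.0
        return np.array(list(itertools.product((-h, h), repeat=3)), dtype=float)


@dataclass(frozen=True)
class PinholeCamera:
    """Ideal pinhole intrinsics.  Camera frame: +z optical axis, +x right, +y down."""

    fx: float = 600.0
    fy: float = 600.0
    cx: float = 320.0
    cy: float = 240.0
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be > 0")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def to_json(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                "w": self.width, "h": self.height}

    @classmethod
    def from_json(cls, obj: dict) -> "PinholeCamera":
        return cls(obj["fx"], obj["fy"], obj["cx"], obj["cy"], obj["w"], obj["h"])


@dataclass
class CornerDetections:
    """Per-corner pixel measurements of one cube in one frame."""

    uv: np.ndarray                    # (8, 2) pixel coords; NaN where not visible
    visible: np.ndarray               # (8,) bool
    noise_sigma_px: float = 0.0
    cube_frame: str = "cube"

    @property
    def n_visible(self) -> int:
        return int(np.count_nonzero(self.visible))

    def to_json(self) -> dict:
        return {
            "uv": [[float(u), float(v)] for u, v in self.uv],
            "visible": [bool(b) for b in self.visible],
            "noise_sigma_px": float(self.noise_sigma_px),
            "cube_frame": self.cube_frame,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CornerDetections":
        return cls(
            np.asarray(obj["uv"], float),
            np.asarray(obj["visible"], bool),
            float(obj["noise_sigma_px"]),
            obj.get("cube_frame", "cube"),
        )


@dataclass(frozen=True)
class TrackingStatus:
    """Whether each of the two cubes yields a pose this frame."""

    reference_tracked: bool
    probe_tracked: bool

    @property
    def both_tracked(self) -> bool:
        return self.reference_tracked and self.probe_tracked


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def project_cube(
    camera: PinholeCamera,
    pose_cam_cube: Pose,
    model: CubeModel,
    noise_sigma_px: float = 0.0,
    rng=None,
) -> CornerDetections:
    """Project cube corners through the pinhole model with Gaussian pixel noise.

    ``pose_cam_cube`` maps cube coordinates into the camera frame.  Corners
    behind the camera or (after noise) outside the image are flagged not
    visible.  A cube centred at or behind the camera plane is an error: the
    simulated camera cannot observe it at all.
    """
    if noise_sigma_px < 0:
        raise ValueError("noise_sigma_px must be >= 0")
    if pose_cam_cube.t[2] <= 0:
        raise ValueError(
            f"cube center must be in front of the camera (z > 0), got z={pose_cam_cube.t[2]:.1f} mm"
        )
    pts = pose_cam_cube.apply(model.corners)          # (8, 3) camera frame
    z = pts[:, 2]
    in_front = z > 1e-9
    uv = np.full((8, 2), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        uv[in_front, 0] = camera.cx + camera.fx * pts[in_front, 0] / z[in_front]
        uv[in_front, 1] = camera.cy + camera.fy * pts[in_front, 1] / z[in_front]
    if noise_sigma_px > 0:
        uv[in_front] += _as_rng(rng).normal(scale=noise_sigma_px, size=(int(in_front.sum()), 2))
    in_image = (
        in_front
        & (uv[:, 0] >= 0) & (uv[:, 0] <= camera.width - 1)
        & (uv[:, 1] >= 0) & (uv[:, 1] <= camera.height - 1)
    )
    uv[~in_image] = np.nan
    return CornerDetections(uv, in_image, noise_sigma_px, cube_frame=pose_cam_cube.child)


def _reproject(camera: PinholeCamera, pts_cam: np.ndarray) -> np.ndarray:
    z = np.maximum(pts_cam[:, 2], 1e-9)
    return np.column_stack(
        (camera.cx + camera.fx * pts_cam[:, 0] / z, camera.cy + camera.fy * pts_cam[:, 1] / z)
    )


def reprojection_rms(
    camera: PinholeCamera, model: CubeModel, pose: Pose, det: CornerDetections
) -> float:
    """RMS pixel residual of a candidate pose against the visible detections."""
    vis = det.visible
    pred = _reproject(camera, pose.apply(model.corners)[vis])
    return float(np.sqrt(np.mean((pred - det.uv[vis]) ** 2)))


def _dlt_init(obj: np.ndarray, xy: np.ndarray) -> tuple[Rotation, np.ndarray] | None:
    """Linear 3D->2D resection from >= 6 points; ``xy`` in normalized image coords."""
    n = obj.shape[0]
    if n < 6:
        return None
    a = np.zeros((2 * n, 12))
    a[0::2, 0:3] = obj
    a[0::2, 3] = 1.0
    a[0::2, 8:11] = -xy[:, 0:1] * obj
    a[0::2, 11] = -xy[:, 0]
    a[1::2, 4:7] = obj
    a[1::2, 7] = 1.0
    a[1::2, 8:11] = -xy[:, 1:2] * obj
    a[1::2, 11] = -xy[:, 1]
    _, _, vt = np.linalg.svd(a)
    p = vt[-1].reshape(3, 4)
    m = p[:, :3]
    scale = 1.0 / np.linalg.norm(m[2])
    if (scale * (m @ obj.mean(axis=0) + p[:, 3]))[2] < 0:
        scale = -scale
    m = scale * m
    u, _, vtm = np.linalg.svd(m)
    r = u @ vtm
    if np.linalg.det(r) < 0:
        r = -r
    t = scale * p[:, 3]
    return Rotation.from_matrix(r), t


def _multistart_inits(obj: np.ndarray, xy: np.ndarray, focal: float, edge: float):
    """Fallback starts when DLT is unavailable (4-5 corners): the 24 cube
    orientations at a depth guessed from the projected corner spread."""
    spread = max(float(np.ptp(xy[:, 0])), float(np.ptp(xy[:, 1])), 1e-6)
    z0 = max(edge / spread, 10.0 * edge)
    center = np.array([xy[:, 0].mean() * z0, xy[:, 1].mean() * z0, z0])
    for rot in Rotation.create_group("O"):
        yield rot, center


def estimate_pose(
    camera: PinholeCamera, model: CubeModel, det: CornerDetections
) -> tuple[Pose | None, float]:
    """Recover the camera-frame cube pose from detected corners.

    Returns ``(pose, reprojection_rms_px)``; ``(None, nan)`` when fewer than
    four corners are visible or the visible corners are collinear in the image
    (the "untrackable" signal driving :class:`TrackingStatus` — not an error).
    The pose minimizes the summed squared reprojection error: DLT-style linear
    initialization (multi-start over the cube's rotation group when fewer than
    six corners are visible), then Levenberg-Marquardt to machine tolerance.
    """
    vis = det.visible
    if det.n_visible < MIN_CORNERS_FOR_POSE:
        return None, float("nan")
    uv = det.uv[vis]
    centered = uv - uv.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-9:
        return None, float("nan")
    obj = model.corners[vis]
    xy = np.column_stack(((uv[:, 0] - camera.cx) / camera.fx, (uv[:, 1] - camera.cy) / camera.fy))

    def residuals(params):
        rot = Rotation.from_rotvec(params[:3])
        pts = rot.apply(obj) + params[3:]
        if np.any(pts[:, 2] <= 1e-6):
            return np.full(2 * obj.shape[0], 1e6)
        return (_reproject(camera, pts) - uv).ravel()

    init = _dlt_init(obj, xy)
    starts = [init] if init is not None else list(
        _multistart_inits(obj, xy, camera.fx, model.edge_length_mm)
    )
    best = None
    for rot0, t0 in starts:
        x0 = np.concatenate([rot0.as_rotvec(), t0])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-20:
            break
    pose = Pose.from_rotation(
        Rotation.from_rotvec(best.x[:3]), best.x[3:], parent="camera", child=det.cube_frame
    )
    rms = float(np.sqrt(best.cost * 2.0 / (2 * obj.shape[0])))
    return pose, rms


def track_frame(
    camera: PinholeCamera,
    ref_pose_world: Pose,
    probe_pose_world: Pose,
    model: CubeModel,
    noise_sigma_px: float = 0.5,
    rng=None,
) -> tuple[TrackingStatus, Pose | None]:
    """Simulate one camera frame observing both cubes.

    Projects and estimates the reference and probe cubes independently; when
    both are trackable, returns the probe pose expressed in the estimated
    reference-cube frame (the quantity the guidance method records).
    Untracked states are ordinary outputs, never exceptions.
    """
    rng = _as_rng(rng)
    try:
        det_ref = project_cube(camera, ref_pose_world, model, noise_sigma_px, rng)
        ref_est, _ = estimate_pose(camera, model, det_ref)
    except ValueError:
        ref_est = None
    try:
        det_probe = project_cube(camera, probe_pose_world, model, noise_sigma_px, rng)
        probe_est, _ = estimate_pose(camera, model, det_probe)
    except ValueError:
        probe_est = None
    status = TrackingStatus(ref_est is not None, probe_est is not None)
    if not status.both_tracked:
        return status, None
    return status, relative_pose(ref_est, probe_est)
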