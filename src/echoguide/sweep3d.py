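"""3D rescue path: motorized fan sweep, volume reconstruction, oblique reslicing.

When the guided 2D view does not show the whole organ, the operator triggers a
motorized fan sweep: the image plane tilts about the probe's lateral (x) axis
from -θ to +θ, producing a wedge of frames.  The frames are compounded into a
voxel volume, which can then be resliced on any oblique plane after the fact —
so an expert can recover the diagnostic view even though the probe itself was
slightly off.

Reconstruction is voxel-driven (reverse mapping): each voxel looks up its
nearest frame plane and samples it bilinearly at the in-plane foot point; a
voxel farther than one voxel from every plane but still inside the swept wedge
is filled with the average of the two bracketing frames, and anything outside
the wedge (or beyond the frame extent) stays a hole.  Reverse mapping avoids
the bin-filling artifacts of forward splatting and is directly checkable
against trilinear samples of the source phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Pose, compose, invert
from .phantom import (
    DEFAULT_MU_PER_MM,
    BModeFrame,
    ImageGeometry,
    Phantom,
    organ_visibility,
    render_bmode,
)

__all__ = [
    "SweepSpec",
    "FrameStack",
    "Volume",
    "capture_sweep",
    "fan_pose",
    "reconstruct",
    "extract_plane",
    "best_plane_search",
    "wedge_plane_candidates",
]

#: The reconstructed volume supports B-mode reslicing only; Doppler and
#: time-motion need live signal acquisition and are unavailable post hoc.
VOLUME_SUPPORTS_DOPPLER = False
VOLUME_SUPPORTS_TIME_MOTION = False


@dataclass(frozen=True)
class SweepSpec:
    """Fan-sweep geometry: tilt about the probe's lateral axis."""

    fan_half_angle_deg: float = 30.0
    n_frames: int = 60
    tilt_axis: str = "x"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a sweep needs at least 2 frames")
        if not 0.0 < self.fan_half_angle_deg <= 60.0:
            raise ValueError("fan half-angle must be in (0, 60] degrees")
        if self.tilt_axis != "x":
            raise ValueError("only tilt about the probe lateral (x) axis is supported")

    @property
    def angles_deg(self) -> np.ndarray:
        th = self.fan_half_angle_deg
        return np.linspace(-th, th, self.n_frames)

    def to_json(self) -> dict:
        return {
            "fan_half_angle_deg": self.fan_half_angle_deg,
            "n_frames": self.n_frames,
            "tilt_axis": self.tilt_axis,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SweepSpec":
        return cls(obj["fan_half_angle_deg"], obj["n_frames"], obj.get("tilt_axis", "x"))


@dataclass
class FrameStack:
    """Ordered sweep frames plus their plane poses (body -> plane)."""

    frames: list
    poses: list
    spec: SweepSpec
    base_pose: Pose
    geometry: ImageGeometry


@dataclass
class Volume:
    """Reconstructed intensity grid, axes aligned with the sweep's base probe frame."""

    data: np.ndarray                  # (nx, ny, nz) float32
    fill: np.ndarray                  # (nx, ny, nz) bool, True where directly observed
    interpolated: np.ndarray          # (nx, ny, nz) bool, wedge voxels filled by averaging
    voxel_mm: float
    origin_pose: Pose                 # body -> volume grid corner
    base_pose: Pose                   # body -> base probe pose of the sweep
    spec: SweepSpec
    geometry: ImageGeometry

    @property
    def has_data(self) -> np.ndarray:
        return self.fill | self.interpolated

    @property
    def hole_fraction(self) -> float:
        """Fraction of voxels not directly observed (outside the wedge or
        farther than the distance threshold from every frame plane)."""
        return 1.0 - float(np.count_nonzero(self.fill)) / self.fill.size


def fan_pose(base_pose: Pose, angle_deg: float) -> Pose:
    """Plane pose of one sweep frame: base pose tilted about the probe x axis."""
    tilt = Pose.from_axis_angle(
        (1.0, 0.0, 0.0), angle_deg, parent=base_pose.child, child=base_pose.child
    )
    return compose(base_pose, tilt)


def capture_sweep(
    phantom: Phantom,
    base_pose: Pose,
    spec: SweepSpec | None = None,
    geometry: ImageGeometry | None = None,
    speckle_seed=None,
    mu_per_mm: float = DEFAULT_MU_PER_MM,
) -> FrameStack:
    """Render the fan of frames around ``base_pose``; deterministic per seed."""
    spec = spec or SweepSpec()
    geometry = geometry or ImageGeometry()
    rng = None if speckle_seed is None else np.random.default_rng(speckle_seed)
    frames, poses = [], []
    for ang in spec.angles_deg:
        pose = fan_pose(base_pose, float(ang))
        frames.append(render_bmode(phantom, pose, geometry, speckle_rng=rng, mu_per_mm=mu_per_mm))
        poses.append(pose)
    return FrameStack(frames, poses, spec, base_pose, geometry)


def reconstruct(stack: FrameStack, voxel_mm: float = 1.0) -> Volume:
    """Compound a fan of frames into a voxel volume (reverse mapping).

    Grid axes are aligned with the base probe frame.  Per voxel: perpendicular
    distance to the nearest frame plane <= ``voxel_mm`` -> bilinear sample of
    that frame; farther but still inside the swept wedge -> mean of the two
    bracketing frames' samples; otherwise a hole.
    """
    if len(stack.frames) < 2:
        raise ValueError("reconstruction needs at least 2 frames")
    angles = np.deg2rad(stack.spec.angles_deg)
    if np.ptp(angles) < 1e-12:
        raise ValueError("degenerate sweep: all frame poses coincide")
    geo = stack.geometry
    th = np.deg2rad(stack.spec.fan_half_angle_deg)

    # wedge bounding box in the base probe frame
    xs = np.array([-geo.width_mm / 2, geo.width_mm / 2])
    zs = np.array([0.0, geo.depth_mm])
    corners = []
    for ang in (-th, 0.0, th):
        for x in xs:
            for z in zs:
                corners.append([x, -np.sin(ang) * z, np.cos(ang) * z])
    corners = np.array(corners)
    lo = corners.min(axis=0) - voxel_mm
    hi = corners.max(axis=0) + voxel_mm
    shape = tuple(int(np.ceil((h - l) / voxel_mm)) for l, h in zip(lo, hi))

    ax = [(np.arange(s) + 0.5) * voxel_mm + l for s, l in zip(shape, lo)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    r = np.hypot(y, z)
    # tilt by +a maps the beam (0,0,1) to (0, -sin a, cos a): phi = atan2(-y, z)
    phi = np.arctan2(-y, z)

    n = stack.spec.n_frames
    frac = (phi + th) / (2 * th) * (n - 1)
    nearest = np.clip(np.rint(frac).astype(int), 0, n - 1)
    lat_idx = (x + geo.width_mm / 2) / geo.pixel_mm - 0.5
    lat_ok = (lat_idx >= -0.5) & (lat_idx <= geo.shape[1] - 0.5)

    data = np.zeros(shape, dtype=np.float32)
    fill = np.zeros(shape, dtype=bool)
    interp = np.zeros(shape, dtype=bool)

    def sample_frame(j: int, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear sample of frame j at the foot points of masked voxels."""
        dphi = phi[mask] - angles[j]
        depth = r[mask] * np.cos(dphi)
        dep_idx = depth / geo.pixel_mm - 0.5
        ok = (dep_idx >= -0.5) & (dep_idx <= geo.shape[0] - 0.5)
        vals = ndimage.map_coordinates(
            stack.frames[j].pixels, np.stack([dep_idx, lat_idx[mask]]),
            order=1, mode="nearest",
        )
        return vals, ok

    for j in range(n):
        mask = (nearest == j) & (r * np.abs(np.sin(phi - angles[j])) <= voxel_mm) & lat_ok
        if not mask.any():
            continue
        vals, ok = sample_frame(j, mask)
        idx = np.where(mask)
        sel = tuple(i[ok] for i in idx)
        data[sel] = vals[ok]
        fill[sel] = True

    # wedge interior beyond the distance threshold: data filled by averaging
    # the bracketing frames, but still counted as holes in the fill mask
    in_wedge = (np.abs(phi) <= th) & lat_ok & ~fill
    if in_wedge.any():
        lo_j = np.clip(np.floor(frac).astype(int), 0, n - 1)
        hi_j = np.clip(lo_j + 1, 0, n - 1)
        for j in range(n):
            mask = in_wedge & (lo_j == j)
            if not mask.any():
                continue
            v1, ok1 = sample_frame(j, mask)
            jh = min(j + 1, n - 1)
            v2, ok2 = sample_frame(jh, mask)
            ok = ok1 & ok2
            idx = np.where(mask)
            sel = tuple(i[ok] for i in idx)
            data[sel] = 0.5 * (v1[ok] + v2[ok])
            interp[sel] = True

    origin = compose(
        stack.base_pose,
        Pose(np.array([1.0, 0, 0, 0]), lo, parent=stack.base_pose.child, child="volume"),
    )
    return Volume(data, fill, interp, float(voxel_mm), origin, stack.base_pose, stack.spec, geo)


def extract_plane(
    volume: Volume, plane_pose: Pose, geometry: ImageGeometry | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reslice the volume on an oblique plane (body-frame pose).

    Returns ``(image, valid)``: trilinear samples on the plane's pixel grid and
    a mask that is False over holes and outside the volume.
    """
    geometry = geometry or volume.geometry
    if plane_pose.parent != volume.origin_pose.parent:
        raise ValueError(
            f"plane pose parent {plane_pose.parent!r} != volume frame {volume.origin_pose.parent!r}"
        )
    pts_body = plane_pose.apply(geometry.plane_points())
    rel = invert(volume.origin_pose)
    pts_vol = rel.rotation.apply(pts_body.reshape(-1, 3)) + rel.t
    idx = (pts_vol / volume.voxel_mm - 0.5).T
    img = ndimage.map_coordinates(volume.data, idx, order=1, mode="constant", cval=0.0)
    filled = ndimage.map_coordinates(
        volume.has_data.astype(np.float32), idx, order=1, mode="constant", cval=0.0
    )
    shape = geometry.shape
    img = img.reshape(shape)
    valid = (filled >= 0.999).reshape(shape)
    img[~valid] = 0.0
    return img, valid


def wedge_plane_candidates(base_pose: Pose, spec: SweepSpec, n_tilts: int = 25) -> list[Pose]:
    """Oblique-plane candidates spanning the swept wedge (tilts about probe x)."""
    return [fan_pose(base_pose, float(a)) for a in
            np.linspace(-spec.fan_half_angle_deg, spec.fan_half_angle_deg, n_tilts)]


def best_plane_search(
    volume: Volume,
    organ_id: str,
    phantom: Phantom,
    search_grid: list[Pose] | None = None,
    geometry: ImageGeometry | None = None,
) -> tuple[Pose, float]:
    """Exhaustive oblique-plane search maximizing organ visibility.

    Models the expert's post-hoc reslicing of the captured wedge: among the
    candidate planes (default: tilts spanning the sweep), return the one whose
    intersection with the organ (per the phantom's geometric ground truth) is
    largest, with its visibility fraction.
    """
    geometry = geometry or volume.geometry
    phantom.spec(organ_id)  # raises KeyError for unknown organs
    if search_grid is None:
        search_grid = wedge_plane_candidates(volume.base_pose, volume.spec)
    if len(search_grid) == 0:
        raise ValueError("empty search grid")
    best_pose, best_vis = None, -1.0
    for pose in search_grid:
        vis = organ_visibility(phantom, organ_id, pose, geometry)
        if vis > best_vis:
            best_pose, best_vis = pose, vis
    return best_pose, float(best_vis)
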