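"""Synthetic body phantom: organ analogs, B-mode image formation, visibility ground truth.

The phantom stands in for the participant's body.  It is a voxel grid of
echogenicity in the body frame (origin at the sternum reference-cube mount,
+x toward the participant's left, +y toward the feet, +z into the body), with
eight axis-aligned ellipsoid organ analogs at anatomy-inspired offsets.

Image formation is deliberately first-order: a B-mode frame is a trilinear
slice of echogenicity with exponential depth attenuation and optional
Rayleigh multiplicative speckle.  Acoustic windows are modeled geometrically:
each organ has a cone of probe orientations from which it is insonatable
(wide for abdominal organs, narrow for the transcranial window); outside the
cone the organ renders at 10% contrast, a bone-shadow proxy, and counts as
invisible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import Pose

__all__ = [
    "OrganSpec",
    "ImageGeometry",
    "Phantom",
    "BModeFrame",
    "default_organ_specs",
    "make_phantom",
    "render_bmode",
    "organ_visibility",
    "aperture_ok",
]

BODY_FRAME = "body"
PROBE_FRAME = "probe_cube"

#: Depth attenuation coefficient, 1/mm (applied as exp(-mu * depth)).
DEFAULT_MU_PER_MM = 0.005
BACKGROUND_ECHO = 0.3
#: Out-of-aperture organs render at this fraction of their contrast.
SHADOW_CONTRAST = 0.1


@dataclass(frozen=True)
class OrganSpec:
    """Geometry and acoustics of one ellipsoidal organ analog.

    ``aw_aperture_deg`` is the half-angle of the cone of probe orientations
    (about ``best_view_dir``) from which the organ can be insonated;
    ``long_axis`` fixes the expert's in-plane probe orientation (the image
    plane contains it).
    """

    organ_id: str
    center_mm: tuple
    radii_mm: tuple
    echogenicity: float
    aw_aperture_deg: float
    long_axis: tuple = (0.0, 1.0, 0.0)
    best_view_dir: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not all(r > 0 for r in self.radii_mm):
            raise ValueError(f"{self.organ_id}: radii must be > 0")
        if not 0.0 <= self.echogenicity <= 1.0:
            raise ValueError(f"{self.organ_id}: echogenicity must be in [0, 1]")
        if not 0.0 < self.aw_aperture_deg <= 90.0:
            raise ValueError(f"{self.organ_id}: aperture must be in (0, 90] degrees")


def default_organ_specs() -> list[OrganSpec]:
    """The eight standard organ analogs.

    Centers/sizes are anatomy-inspired (superficial vessels shallow and thin,
    heart left-thoracic, abdominal organs deep, transcranial target with a 5°
    aperture); none of the study-level guarantees depend on the exact values.
    """
    return [
        OrganSpec("carotid", (60, -120, 25), (6, 30, 6), 0.12, 20.0),
        OrganSpec("femoral", (90, 170, 30), (7, 35, 7), 0.12, 20.0),
        OrganSpec("lv_long_axis", (-55, 20, 60), (30, 40, 25), 0.55, 20.0),
        OrganSpec("four_chamber", (-60, 105, 65), (35, 35, 28), 0.50, 20.0),
        OrganSpec("cerebral", (100, -140, 60), (15, 15, 15), 0.35, 5.0),
        OrganSpec("portal_vein", (45, 40, 65), (10, 40, 10), 0.12, 30.0),
        OrganSpec("aorta", (-5, 90, 95), (9, 50, 9), 0.08, 30.0),
        OrganSpec("kidney", (85, 110, 85), (25, 45, 18), 0.45, 30.0),
    ]


@dataclass(frozen=True)
class ImageGeometry:
    """B-mode frame geometry: lateral width x axial depth, square pixels."""

    depth_mm: float = 140.0
    width_mm: float = 100.0
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.depth_mm, self.width_mm, self.pixel_mm) <= 0:
            raise ValueError("geometry dimensions must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (round(self.depth_mm / self.pixel_mm), round(self.width_mm / self.pixel_mm))

    def plane_points(self) -> np.ndarray:
        """Pixel-center coordinates in the probe frame, shape (n_depth, n_lat, 3).

        The image plane is the probe frame's x-z plane: x lateral (centred),
        z depth into the body, y the elevation (plane normal).
        """
        nd, nl = self.shape
        xs = -self.width_mm / 2.0 + (np.arange(nl) + 0.5) * self.pixel_mm
        zs = (np.arange(nd) + 0.5) * self.pixel_mm
        x, z = np.meshgrid(xs, zs)
        return np.stack([x, np.zeros_like(x), z], axis=-1)


@dataclass
class Phantom:
    """Voxel body phantom in the body frame."""

    grid: np.ndarray                      # float32 echogenicity, (nx, ny, nz)
    label_grid: np.ndarray                # int16 organ index (0 = background)
    spacing_mm: float
    origin_mm: np.ndarray                 # body-frame position of voxel (0,0,0) corner
    specs: list
    frame: str = BODY_FRAME
    expert_poses: dict = field(default_factory=dict)     # organ_id -> Pose (body -> probe)
    max_section_area: dict = field(default_factory=dict)  # organ_id -> mm^2

    @property
    def organ_ids(self) -> list[str]:
        return [s.organ_id for s in self.specs]

    def spec(self, organ_id: str) -> OrganSpec:
        for s in self.specs:
            if s.organ_id == organ_id:
                return s
        raise KeyError(f"unknown organ {organ_id!r}; phantom has {self.organ_ids}")

    def label_of(self, organ_id: str) -> int:
        return self.organ_ids.index(organ_id) + 1

    def voxel_coords(self, points_body: np.ndarray) -> np.ndarray:
        """Body-frame mm -> fractional voxel indices (voxel centers at i+0.5)."""
        return (points_body - self.origin_mm) / self.spacing_mm - 0.5


@dataclass
class BModeFrame:
    """One simulated B-mode image plus the probe pose it was captured at."""

    pixels: np.ndarray                    # (n_depth, n_lateral) in [0, 1]
    geometry: ImageGeometry
    probe_pose: Pose                      # body -> probe at capture time

    def __post_init__(self) -> None:
        if self.pixels.shape != self.geometry.shape:
            raise ValueError(
                f"pixel array {self.pixels.shape} inconsistent with geometry {self.geometry.shape}"
            )


DEFAULT_BOUNDS = ((-150.0, 150.0), (-160.0, 230.0), (0.0, 150.0))


def make_phantom(
    specs: list[OrganSpec] | None = None,
    spacing_mm: float = 2.0,
    seed: int = 0,
    bounds=DEFAULT_BOUNDS,
    geometry: ImageGeometry | None = None,
) -> Phantom:
    """Build the voxel phantom: smooth background plus painted organ ellipsoids.

    Deterministic given ``seed``.  Each organ's expert pose (probe on the skin
    above the organ center, beam along the best-view axis, image plane
    containing the organ's long axis) and its reference section area (the
    organ's visible area at that pose, the denominator of
    :func:`organ_visibility`) are precomputed here.
    """
    if specs is None:
        specs = default_organ_specs()
    geometry = geometry or ImageGeometry()
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    shape = tuple(int(round((h - l) / spacing_mm)) for l, h in zip(lo, hi))

    # smooth background: coarse Gaussian noise upsampled, +/-0.05 around 0.3
    coarse = rng.standard_normal([max(2, s // 12) for s in shape])
    coarse = ndimage.gaussian_filter(coarse, sigma=1.0)
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    texture = ndimage.zoom(coarse, zoom, order=1)[: shape[0], : shape[1], : shape[2]]
    texture = texture / max(1e-9, np.abs(texture).max())
    grid = (BACKGROUND_ECHO + 0.05 * texture).astype(np.float32)
    label = np.zeros(shape, dtype=np.int16)

    axes_mm = [lo[d] + (np.arange(shape[d]) + 0.5) * spacing_mm for d in range(3)]

    seen = set()
    for idx, spec in enumerate(specs, start=1):
        if spec.organ_id in seen:
            raise ValueError(f"duplicate organ id {spec.organ_id!r}")
        seen.add(spec.organ_id)
        c = np.asarray(spec.center_mm, float)
        r = np.asarray(spec.radii_mm, float)
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(
                f"organ {spec.organ_id!r} (center {c.tolist()}, radii {r.tolist()}) "
                f"extends outside the phantom bounds {bounds}"
            )
        # paint within the organ's bounding box only
        sl, local = [], []
        for d in range(3):
            i0 = int(np.searchsorted(axes_mm[d], c[d] - r[d] - spacing_mm))
            i1 = int(np.searchsorted(axes_mm[d], c[d] + r[d] + spacing_mm))
            sl.append(slice(i0, i1))
            local.append((axes_mm[d][i0:i1] - c[d]) / r[d])
        u, v, w = np.meshgrid(*local, indexing="ij")
        inside = u**2 + v**2 + w**2 <= 1.0
        grid[tuple(sl)][inside] = spec.echogenicity
        label[tuple(sl)][inside] = idx

    phantom = Phantom(grid, label, float(spacing_mm), lo, list(specs))
    for spec in specs:
        pose = _expert_pose(spec)
        phantom.expert_poses[spec.organ_id] = pose
        area = _section_area(phantom, spec.organ_id, pose, geometry)
        if area <= 0:
            raise ValueError(f"organ {spec.organ_id!r} is not visible at its expert pose")
        phantom.max_section_area[spec.organ_id] = area
    return phantom


def _expert_pose(spec: OrganSpec) -> Pose:
    """Ideal acquisition pose: probe on the skin above the organ center, beam
    along the best-view axis, image plane containing the organ's long axis."""
    z_axis = np.asarray(spec.best_view_dir, float)
    z_axis = z_axis / np.linalg.norm(z_axis)
    la = np.asarray(spec.long_axis, float)
    x_axis = la - (la @ z_axis) * z_axis
    n = np.linalg.norm(x_axis)
    if n < 1e-9:
        x_axis = np.array([1.0, 0.0, 0.0])
    else:
        x_axis = x_axis / n
    y_axis = np.cross(z_axis, x_axis)
    rot = Rotation.from_matrix(np.column_stack([x_axis, y_axis, z_axis]))
    cx, cy, _ = spec.center_mm
    return Pose.from_rotation(rot, (cx, cy, 0.0), parent=BODY_FRAME, child=PROBE_FRAME)


def aperture_ok(spec: OrganSpec, probe_pose: Pose) -> bool:
    """Acoustic-window cone test, anchored at the organ.

    The window is a cone of half-angle ``aw_aperture_deg`` about the organ's
    best-view axis with its apex at the organ center: insonation succeeds only
    if (a) the beam direction lies within the cone, and (b) the ray from the
    probe's entry point to the organ center does too — i.e. the probe stands
    on the small skin patch through which the organ is reachable.  A narrow
    cone therefore punishes both orientation and position errors, which is
    what makes a deep target behind a small bone window hard; wide abdominal
    cones tolerate centimetre-scale offsets.
    """
    best = np.asarray(spec.best_view_dir, float)
    best = best / np.linalg.norm(best)
    cos_ap = np.cos(np.deg2rad(spec.aw_aperture_deg))
    beam = probe_pose.rotation.as_matrix()[:, 2]
    if float(beam @ best) < cos_ap - 1e-12:
        return False
    to_center = np.asarray(spec.center_mm, float) - probe_pose.t
    norm = np.linalg.norm(to_center)
    if norm < 1e-9:
        return True
    return float(to_center / norm @ best) >= cos_ap - 1e-12


def _sample(phantom: Phantom, points_body: np.ndarray, order: int, grid: np.ndarray) -> np.ndarray:
    coords = phantom.voxel_coords(points_body.reshape(-1, 3)).T
    out = ndimage.map_coordinates(grid, coords, order=order, mode="constant", cval=0.0)
    return out.reshape(points_body.shape[:-1])


def render_bmode(
    phantom: Phantom,
    probe_pose: Pose,
    geometry: ImageGeometry | None = None,
    speckle_rng=None,
    mu_per_mm: float = DEFAULT_MU_PER_MM,
) -> BModeFrame:
    """Form a B-mode frame at a probe pose (body -> probe).

    Intensity = trilinear echogenicity sample x exp(-mu * depth), with organs
    whose aperture test fails for this orientation pulled to 10% contrast
    against the nominal background (bone-shadow proxy).  Rayleigh
    multiplicative speckle (unit mean) is applied when ``speckle_rng`` is
    given.  Samples outside the phantom are 0.  Values are clipped to [0, 1].
    """
    geometry = geometry or ImageGeometry()
    if probe_pose.parent != phantom.frame:
        raise ValueError(
            f"probe pose parent frame {probe_pose.parent!r} != phantom frame {phantom.frame!r}"
        )
    pts_probe = geometry.plane_points()
    pts_body = probe_pose.apply(pts_probe)
    vals = _sample(phantom, pts_body, order=1, grid=phantom.grid).astype(float)

    shadowed = [s for s in phantom.specs if not aperture_ok(s, probe_pose)]
    if shadowed:
        labels = _sample(phantom, pts_body, order=0, grid=phantom.label_grid.astype(np.float32))
        for s in shadowed:
            mask = labels == phantom.label_of(s.organ_id)
            vals[mask] = BACKGROUND_ECHO + SHADOW_CONTRAST * (vals[mask] - BACKGROUND_ECHO)

    depth = pts_probe[..., 2]
    vals *= np.exp(-mu_per_mm * depth)
    if speckle_rng is not None:
        rng = speckle_rng if isinstance(speckle_rng, np.random.Generator) else np.random.default_rng(speckle_rng)
        # Rayleigh with unit mean: scale = sqrt(2/pi)
        vals *= rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=vals.shape)
    return BModeFrame(np.clip(vals, 0.0, 1.0), geometry, probe_pose)


def _section_area(phantom: Phantom, organ_id: str, plane: Pose, geometry: ImageGeometry) -> float:
    """Area (mm^2) of the organ's label region intersected by the image plane."""
    pts_body = plane.apply(geometry.plane_points())
    labels = _sample(phantom, pts_body, order=0, grid=phantom.label_grid.astype(np.float32))
    n = int(np.count_nonzero(labels == phantom.label_of(organ_id)))
    return n * geometry.pixel_mm**2


def organ_visibility(
    phantom: Phantom, organ_id: str, plane: Pose, geometry: ImageGeometry | None = None
) -> float:
    """Fraction of the organ's best-view cross-section visible in a plane.

    0 when the plane misses the organ or the acoustic-window aperture test
    fails (outside the cone the image shows only the bone-shadow proxy,
    so nothing diagnostically visible).  1 at the organ's expert pose by
    construction (the denominator is precomputed there).
    """
    geometry = geometry or ImageGeometry()
    if plane.parent != phantom.frame:
        raise ValueError(
            f"plane pose parent frame {plane.parent!r} != phantom frame {phantom.frame!r}"
        )
    spec = phantom.spec(organ_id)
    if not aperture_ok(spec, plane):
        return 0.0
    area = _section_area(phantom, organ_id, plane, geometry)
    return float(min(1.0, area / phantom.max_section_area[organ_id]))
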