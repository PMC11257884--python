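"""Rigid-transform (SE(3)) core: named frames, composition, relative poses, error metrics.

The probe-guidance method rests on one invariant: the probe pose expressed in
the body-mounted reference-cube frame is independent of where the camera sits.
Everything downstream (target saving, marker alignment, sweep geometry) is a
chain of rigid transforms, so poses carry explicit frame labels and every
composition checks that the chain is consistent.  Conventions: right-handed
coordinates, millimetres, unit quaternions stored scalar-first with the scalar
component canonicalized to be non-negative (unique representation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation


class FrameMismatchError(ValueError):
    """Raised when pose frame labels do not chain as required."""


def _canonical_quat(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float).reshape(4)
    n = float(np.linalg.norm(q))
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError(f"quaternion has invalid norm {n!r}")
    q = q / n
    # sign canonicalization: scalar part >= 0; if it is zero, first nonzero
    # vector component positive.
    if q[0] < 0:
        q = -q
    elif q[0] == 0:
        nz = np.flatnonzero(q)
        if nz.size and q[nz[0]] < 0:
            q = -q
    return q


@dataclass(frozen=True)
class Pose:
    """Rigid transform mapping points in `child` coordinates into `parent`.

    Parameters
    ----------
    q : array-like, shape (4,)
        Unit quaternion, scalar-first ``[w, x, y, z]``.  Normalized and
        sign-canonicalized on construction.
    t : array-like, shape (3,)
        Translation in millimetres.
    parent, child : str
        Frame labels.  ``compose`` requires ``a.child == b.parent``.
    """

    q: np.ndarray
    t: np.ndarray
    parent: str = "world"
    child: str = "body"

    def __post_init__(self) -> None:
        q = _canonical_quat(self.q)
        t = np.asarray(self.t, dtype=float).reshape(3).copy()
        q.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "t", t)

    # --- constructors -----------------------------------------------------
    @classmethod
    def identity(cls, parent: str = "world", child: str = "world") -> "Pose":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3), parent, child)

    @classmethod
    def from_rotation(
        cls, rot: Rotation, t=(0.0, 0.0, 0.0), parent: str = "world", child: str = "body"
    ) -> "Pose":
        return cls(rot.as_quat(scalar_first=True), t, parent, child)

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, t=(0.0, 0.0, 0.0), parent: str = "world", child: str = "body"
    ) -> "Pose":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
        return cls.from_rotation(rot, t, parent, child)

    @classmethod
    def from_matrix(cls, m, parent: str = "world", child: str = "body") -> "Pose":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {m.shape}")
        rot = Rotation.from_matrix(m[:3, :3])
        return cls.from_rotation(rot, m[:3, 3], parent, child)

    # --- views ------------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.q, scalar_first=True)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation.as_matrix()
        m[:3, 3] = self.t
        return m

    def relabel(self, parent: str | None = None, child: str | None = None) -> "Pose":
        """Re-declare frame labels (trust boundary; geometry unchanged)."""
        return Pose(
            self.q,
            self.t,
            self.parent if parent is None else parent,
            self.child if child is None else child,
        )

    def apply(self, points) -> np.ndarray:
        """Map points (…, 3) in the child frame into the parent frame."""
        pts = np.array(points, dtype=float, copy=True)
        return self.rotation.apply(pts.reshape(-1, 3)).reshape(pts.shape) + self.t

    def to_json(self) -> dict:
        return {
            "q": [float(v) for v in self.q],
            "t": [float(v) for v in self.t],
            "parent": self.parent,
            "child": self.child,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Pose":
        return cls(np.asarray(obj["q"], float), np.asarray(obj["t"], float), obj["parent"], obj["child"])


@dataclass(frozen=True)
class PoseError:
    """Decomposed difference between two poses sharing the same frames."""

    translation_mm: float
    rotation_deg: float


def compose(a: Pose, b: Pose) -> Pose:
    """Chain two transforms: the result maps ``b.child`` into ``a.parent``."""
    if a.child != b.parent:
        raise FrameMismatchError(
            f"cannot compose: left pose child frame {a.child!r} != right pose parent frame {b.parent!r}"
        )
    ra, rb = a.rotation, b.rotation
    return Pose((ra * rb).as_quat(scalar_first=True), ra.apply(b.t.copy()) + a.t, a.parent, b.child)


def invert(p: Pose) -> Pose:
    """Inverse transform; parent and child frames swap."""
    rinv = p.rotation.inv()
    return Pose(rinv.as_quat(scalar_first=True), -rinv.apply(p.t.copy()), p.child, p.parent)


def relative_pose(reference: Pose, probe: Pose) -> Pose:
    """Express ``probe`` in the frame of ``reference``.

    Both poses must share the same parent (the camera/world frame).  The
    result is ``invert(reference) ∘ probe`` — by construction invariant to any
    common motion applied to both inputs, which is what makes the guidance
    method independent of camera placement.
    """
    if reference.parent != probe.parent:
        raise FrameMismatchError(
            f"relative_pose needs a common parent: {reference.parent!r} != {probe.parent!r}"
        )
    return compose(invert(reference), probe)


def quaternion_angle_deg(qa: np.ndarray, qb: np.ndarray) -> float:
    """Geodesic angle between two unit quaternions, in degrees, in [0, 180].

    Uses the chord form ``theta = 4*asin(||qa -/+ qb|| / 2)``, which keeps full
    precision for tiny angles where ``2*acos(|<qa,qb>|)`` loses ~8 digits.
    """
    m = min(float(np.linalg.norm(qa - qb)), float(np.linalg.norm(qa + qb)))
    return float(np.degrees(4.0 * np.arcsin(min(1.0, m / 2.0))))


def pose_error(a: Pose, b: Pose) -> PoseError:
    """Translation distance (mm) and rotation angle (deg) between two poses."""
    if a.parent != b.parent or a.child != b.child:
        raise FrameMismatchError(
            f"pose_error needs matching frames: ({a.parent!r}->{a.child!r}) vs ({b.parent!r}->{b.child!r})"
        )
    return PoseError(
        float(np.linalg.norm(a.t - b.t)),
        quaternion_angle_deg(a.q, b.q),
    )


def interpolate_pose(a: Pose, b: Pose, frac: float) -> Pose:
    """Geodesic interpolation from ``a`` toward ``b`` (lerp translation, slerp rotation).

    ``frac`` = 0 gives ``a``, 1 gives ``b``.  Used by the simulated-operator
    controller, which closes a fixed fraction of the pose error per step.
    """
    if a.parent != b.parent or a.child != b.child:
        raise FrameMismatchError("interpolate_pose needs matching frames")
    ra, rb = a.rotation, b.rotation
    delta = (ra.inv() * rb).as_rotvec()
    rot = ra * Rotation.from_rotvec(frac * delta)
    t = (1.0 - frac) * a.t + frac * b.t
    return Pose(rot.as_quat(scalar_first=True), t, a.parent, a.child)


def random_pose(
    rng: np.random.Generator,
    translation_scale_mm: float = 100.0,
    parent: str = "world",
    child: str = "body",
) -> Pose:
    """Uniformly random rotation with a Gaussian translation; test helper."""
    rot = Rotation.random(rng=rng)
    t = rng.normal(scale=translation_scale_mm, size=3)
    return Pose.from_rotation(rot, t, parent, child)


def poses_allclose(a: Pose, b: Pose, atol_mm: float = 1e-9, atol_deg: float = 1e-9) -> bool:
    err = pose_error(a, b)
    return err.translation_mm <= atol_mm and err.rotation_deg <= atol_deg


def transform_points(pose: Pose, points: Iterable) -> np.ndarray:
    return pose.apply(np.asarray(list(points) if not isinstance(points, np.ndarray) else points))
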