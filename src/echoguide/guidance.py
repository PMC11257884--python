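"""The guidance protocol: target acquisition, four-marker alignment, HMI state.

During acquisition an expert saves the probe pose (expressed in the
body-mounted reference-cube frame) that yields the ideal view of each organ.
During restitution a novice moves the probe until four virtual markers rigidly
attached to the probe coincide, one by one, with the four saved marker
positions; when every marker is within tolerance the pose is "locked" and the
reference image is shown for comparison.

Why four points rather than a pose error pair: a per-marker distance is a
single intuitive quantity that can be rendered as a sphere-in-cube cue, and a
bound on all four distances simultaneously bounds both the translation and the
rotation of the probe (see :func:`rotation_lock_bound_deg`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import FrameMismatchError, Pose, PoseError, pose_error

__all__ = [
    "MarkerLayout",
    "TargetRecord",
    "AlignmentState",
    "HmiState",
    "Session",
    "ORGAN_IDS",
    "DEFAULT_TOLERANCE_MM",
    "marker_points",
    "alignment_state",
    "rotation_lock_bound_deg",
    "hmi_update",
]

logger = logging.getLogger(__name__)

ORGAN_IDS = (
    "carotid",
    "femoral",
    "lv_long_axis",
    "four_chamber",
    "cerebral",
    "portal_vein",
    "aorta",
    "kidney",
)

#: Per-marker alignment tolerance, mm.  The reference-cube support structure
#: repositions the cube only to within ~10 mm between sessions, so a
#: same-order-of-magnitude lock threshold is used; it is configurable and all
#: study-level conclusions are checked as orderings, not absolute thresholds.
DEFAULT_TOLERANCE_MM = 5.0

REFERENCE_FRAME = "reference_cube"
PROBE_FRAME = "probe_cube"


@dataclass(frozen=True)
class MarkerLayout:
    """Four guidance-marker points fixed in the probe-cube frame (mm).

    Default: corners of a 40 mm square centred on the cube origin, parallel to
    the cube's top face.  Centring the square's centroid exactly on the origin
    makes the locked-state translation bound exact.  A larger marker radius
    improves rotation observability (a given angular error moves the markers
    further).
    """

    points: np.ndarray = field(
        default_factory=lambda: np.array(
            [[20.0, 20.0, 0.0], [-20.0, 20.0, 0.0], [-20.0, -20.0, 0.0], [20.0, -20.0, 0.0]]
        )
    )

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(4, 3).copy()
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValueError("marker layout points must not be collinear")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def radius_mm(self) -> float:
        """Largest marker distance from the layout centroid."""
        return float(np.linalg.norm(self.points - self.centroid, axis=1).max())

    @property
    def effective_radius_mm(self) -> float:
        """Worst-case rotation lever arm: min over axes through the centroid of
        the largest marker distance to the axis.

        For the default square this is the half side (20 mm), attained for an
        edge-parallel axis, not the corner radius (28.3 mm): a rotation about
        an edge-parallel axis moves every marker by only ``2*(s/2)*sin(θ/2)``.
        """
        centered = self.points - self.centroid
        # candidate axes: dense unit sphere sample plus the layout's own
        # principal directions, which contain the minimizer for symmetric
        # layouts.
        k = np.arange(2048)
        phi = np.arccos(1 - 2 * (k + 0.5) / 2048)
        theta = np.pi * (1 + 5**0.5) * k
        axes = np.column_stack(
            (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
        )
        _, _, vt = np.linalg.svd(centered)
        edge_dirs = []
        for i in range(4):
            for j in range(i + 1, 4):
                d = centered[i] - centered[j]
                n = np.linalg.norm(d)
                if n > 1e-9:
                    edge_dirs.append(d / n)
        axes = np.vstack([axes, vt, centered / np.linalg.norm(centered, axis=1, keepdims=True),
                          np.asarray(edge_dirs)])
        # distance of each marker to each axis
        proj = axes @ centered.T                            # (n_axes, 4)
        d2 = (centered**2).sum(axis=1)[None, :] - proj**2
        return float(np.sqrt(np.clip(d2, 0, None).max(axis=1)).min())


@dataclass(frozen=True)
class TargetRecord:
    """An organ's expert-saved probe pose (reference-cube frame) + reference image."""

    organ_id: str
    saved_relative: Pose
    reference_image_id: str = ""
    created_by: str = "expert"

    def __post_init__(self) -> None:
        _check_relative_frames(self.saved_relative, "saved_relative")

    def to_json(self) -> dict:
        return {
            "organ_id": self.organ_id,
            "saved_relative": self.saved_relative.to_json(),
            "reference_image_id": self.reference_image_id,
            "created_by": self.created_by,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TargetRecord":
        return cls(
            obj["organ_id"],
            Pose.from_json(obj["saved_relative"]),
            obj.get("reference_image_id", ""),
            obj.get("created_by", "expert"),
        )


def _check_relative_frames(p: Pose, what: str) -> None:
    if p.parent != REFERENCE_FRAME or p.child != PROBE_FRAME:
        raise FrameMismatchError(
            f"{what} must be the probe-cube pose in the reference-cube frame "
            f"({REFERENCE_FRAME!r} -> {PROBE_FRAME!r}), got {p.parent!r} -> {p.child!r}"
        )


class Session:
    """Ordered collection of acquisition targets, one per organ."""

    def __init__(self, session_id: str = "session") -> None:
        self.session_id = session_id
        self._targets: dict[str, TargetRecord] = {}

    def save_target(
        self, organ_id: str, relative: Pose, reference_image_id: str = "", created_by: str = "expert"
    ) -> TargetRecord:
        """Store the expert's saved pose for an organ; re-saving overwrites with a warning."""
        record = TargetRecord(organ_id, relative, reference_image_id, created_by)
        if organ_id in self._targets:
            logger.warning("overwriting previously saved target for organ %r", organ_id)
        self._targets[organ_id] = record
        return record

    def __len__(self) -> int:
        return len(self._targets)

    def __contains__(self, organ_id: str) -> bool:
        return organ_id in self._targets

    def get(self, organ_id: str) -> TargetRecord:
        return self._targets[organ_id]

    @property
    def targets(self) -> list[TargetRecord]:
        return list(self._targets.values())


@dataclass(frozen=True)
class AlignmentState:
    """Restitution-phase feedback: per-marker distances and the lock flag."""

    per_marker_distance_mm: np.ndarray        # (4,)
    per_marker_green: np.ndarray              # (4,) bool
    locked: bool
    pose_err: PoseError
    tolerance_mm: float
    translation_delta_mm: np.ndarray          # target - current translation, reference frame


@dataclass(frozen=True)
class HmiState:
    """What the novice-facing interface displays for one frame."""

    tracking_notifications: dict
    instruction: str
    context_organ: str
    show_reference_image: bool


def marker_points(relative: Pose, layout: MarkerLayout | None = None) -> np.ndarray:
    """Marker positions in the reference-cube frame for a given relative pose."""
    _check_relative_frames(relative, "relative")
    layout = layout or MarkerLayout()
    return relative.apply(layout.points)


def alignment_state(
    target: TargetRecord,
    current: Pose,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    layout: MarkerLayout | None = None,
) -> AlignmentState:
    """Compare current probe pose against the saved target marker-by-marker.

    A marker is green when its distance to the saved marker position is within
    tolerance; the pose locks when all four are green.
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be > 0")
    layout = layout or MarkerLayout()
    saved_pts = marker_points(target.saved_relative, layout)
    cur_pts = marker_points(current, layout)
    dist = np.linalg.norm(saved_pts - cur_pts, axis=1)
    green = dist <= tolerance_mm
    return AlignmentState(
        per_marker_distance_mm=dist,
        per_marker_green=green,
        locked=bool(green.all()),
        pose_err=pose_error(target.saved_relative, current),
        tolerance_mm=float(tolerance_mm),
        translation_delta_mm=target.saved_relative.t - current.t,
    )


def rotation_lock_bound_deg(tolerance_mm: float, layout: MarkerLayout | None = None) -> float:
    """Largest rotation error compatible with a locked state.

    When all four marker distances are within ``tolerance_mm`` the relative
    rotation angle is at most ``2*asin(tol / (2*r_eff))`` with ``r_eff`` the
    layout's worst-case lever arm (:attr:`MarkerLayout.effective_radius_mm`);
    guaranteed for centrally symmetric layouts such as the default square.
    The translation error is simultaneously bounded by ``tolerance_mm`` itself
    (the layout centroid sits at the origin, so the mean marker displacement
    is exactly the translation error).
    """
    layout = layout or MarkerLayout()
    s = min(1.0, tolerance_mm / (2.0 * layout.effective_radius_mm))
    return float(np.degrees(2.0 * np.arcsin(s)))


#: Rotation error (deg) above which the HMI appends a tilt hint.
TILT_HINT_THRESHOLD_DEG = 5.0

_AXIS_HINTS = {
    (0, 1): "move right",
    (0, -1): "move left",
    (1, 1): "move down toward the feet",
    (1, -1): "move up toward the head",
    (2, 1): "press deeper",
    (2, -1): "lift the probe",
}


def hmi_update(status, align: AlignmentState | None, organ: str) -> HmiState:
    """Deterministic instruction selection for the novice-facing display.

    Directional hints are computed in the reference-cube (body) frame so that
    "move left" is reproducible regardless of where the camera stands.
    """
    notes = {
        "reference_cube": "tracked" if status.reference_tracked else "NOT TRACKED",
        "probe_cube": "tracked" if status.probe_tracked else "NOT TRACKED",
    }
    if not status.both_tracked:
        missing = [name for name, ok in (
            ("reference cube", status.reference_tracked), ("probe cube", status.probe_tracked)
        ) if not ok]
        instruction = f"aim camera at both cubes (lost: {', '.join(missing)})"
        return HmiState(notes, instruction, organ, show_reference_image=False)
    if align is None:
        raise ValueError("alignment state required when both cubes are tracked")
    if align.locked:
        return HmiState(
            notes, "hold position; compare with reference image", organ, show_reference_image=True
        )
    delta = align.translation_delta_mm
    axis = int(np.argmax(np.abs(delta)))
    instruction = _AXIS_HINTS[(axis, int(np.sign(delta[axis])) or 1)]
    if align.pose_err.rotation_deg > TILT_HINT_THRESHOLD_DEG:
        instruction += "; tilt the probe to match orientation"
    return HmiState(notes, instruction, organ, show_reference_image=False)
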