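"""File formats and configuration: target sessions (JSON), volumes (NIfTI),
frames (PNG + JSON pose sidecar), study tables (CSV), session config.

Poses serialize as ``{"q": [w,x,y,z], "t": [x,y,z], "parent", "child"}`` with
full double precision (json round-trips Python floats bit-exactly).  All
readers validate structure explicitly and raise :class:`SessionFormatError`
naming the offending field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .fiducial import PinholeCamera
from .geometry import Pose
from .guidance import DEFAULT_TOLERANCE_MM, MarkerLayout, TargetRecord
from .phantom import BModeFrame, ImageGeometry, Phantom
from .study import DriftModel, NoviceModel, ScoreThresholds
from .sweep3d import SweepSpec, Volume

__all__ = [
    "SessionFormatError",
    "SessionConfig",
    "read_targets",
    "write_targets",
    "save_volume",
    "load_volume_grid",
    "save_phantom",
    "save_frame",
    "load_frame",
    "spawn_seeds",
]


class SessionFormatError(ValueError):
    """A session/config file violates the expected structure."""


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


# --- target session files -------------------------------------------------

_POSE_KEYS = {"q": 4, "t": 3}


def _validate_pose(obj, where: str) -> Pose:
    if not isinstance(obj, dict):
        raise SessionFormatError(f"{where}: expected a pose object, got {type(obj).__name__}")
    for key, n in _POSE_KEYS.items():
        if key not in obj:
            raise SessionFormatError(f"{where}: missing field {key!r}")
        vals = obj[key]
        if not isinstance(vals, list) or len(vals) != n or not all(
            isinstance(v, (int, float)) for v in vals
        ):
            raise SessionFormatError(f"{where}: field {key!r} must be a list of {n} numbers")
    for key in ("parent", "child"):
        if key not in obj or not isinstance(obj[key], str):
            raise SessionFormatError(f"{where}: missing or non-string field {key!r}")
    try:
        return Pose.from_json(obj)
    except ValueError as exc:
        raise SessionFormatError(f"{where}: {exc}") from exc


def write_targets(records: list[TargetRecord], path, session_id: str = "session") -> None:
    """Write an acquisition session: insertion-ordered target records."""
    import datetime

    payload = {
        "session_id": session_id,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "targets": [r.to_json() for r in records],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_targets(path) -> list[TargetRecord]:
    """Read and validate an acquisition session; errors name the bad field."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"session file not found: {p}")
    try:
        obj = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"{p}: not valid JSON ({exc})") from exc
    if not isinstance(obj, dict) or "targets" not in obj:
        raise SessionFormatError(f"{p}: missing field 'targets'")
    records = []
    seen = set()
    for i, t in enumerate(obj["targets"]):
        where = f"{p}: targets[{i}]"
        if not isinstance(t, dict):
            raise SessionFormatError(f"{where}: expected an object")
        for key in ("organ_id", "saved_relative"):
            if key not in t:
                raise SessionFormatError(f"{where}: missing field {key!r}")
        if t["organ_id"] in seen:
            raise SessionFormatError(f"{where}: duplicate organ_id {t['organ_id']!r}")
        seen.add(t["organ_id"])
        pose = _validate_pose(t["saved_relative"], f"{where}.saved_relative")
        records.append(
            TargetRecord(
                t["organ_id"], pose, t.get("reference_image_id", ""), t.get("created_by", "expert")
            )
        )
    return records


# --- volumes and phantoms (NIfTI) ----------------------------------------


def _affine(spacing: float, origin: np.ndarray) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: Volume, path) -> None:
    """Store a reconstructed volume (plus its fill mask and poses) as NIfTI + JSON."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_mm, volume.origin_pose.t))
    nib.save(img, str(path))
    meta = {
        "voxel_mm": volume.voxel_mm,
        "origin_pose": volume.origin_pose.to_json(),
        "base_pose": volume.base_pose.to_json(),
        "sweep": volume.spec.to_json(),
        "geometry": asdict(volume.geometry),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    # mask codes: 0 = hole, 1 = interpolated (wedge-averaged), 2 = observed
    mask = volume.fill.astype(np.uint8) * 2
    mask[volume.interpolated & ~volume.fill] = 1
    nib.save(
        nib.Nifti1Image(mask, _affine(volume.voxel_mm, volume.origin_pose.t)),
        str(path.with_name(path.stem + "_mask.nii")),
    )


def load_volume_grid(path) -> tuple[np.ndarray, np.ndarray]:
    """Load the intensity grid and affine of a stored volume."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), img.affine


def save_phantom(phantom: Phantom, path_echo, path_labels) -> None:
    aff = _affine(phantom.spacing_mm, phantom.origin_mm)
    nib.save(nib.Nifti1Image(phantom.grid.astype(np.float32), aff), str(path_echo))
    nib.save(nib.Nifti1Image(phantom.label_grid.astype(np.int16), aff), str(path_labels))


# --- frames (PNG + pose sidecar) ------------------------------------------


def save_frame(frame: BModeFrame, path) -> None:
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.clip(frame.pixels, 0, 1) * 255).astype(np.uint8))
    sidecar = {
        "probe_pose": frame.probe_pose.to_json(),
        "geometry": asdict(frame.geometry),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_frame(path) -> BModeFrame:
    import imageio.v3 as iio

    path = Path(path)
    pixels = iio.imread(path).astype(np.float32) / 255.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return BModeFrame(
        pixels, ImageGeometry(**meta["geometry"]), Pose.from_json(meta["probe_pose"])
    )


# --- session configuration -------------------------------------------------

_RANGES = {
    "tolerance_mm": (0.0, 50.0),
    "perfect_visibility": (0.0, 1.0),
    "tracking_noise_px": (0.0, 10.0),
    "placement_radius_mm": (0.0, 100.0),
    "respiration_amplitude_mm": (0.0, 50.0),
    "step_gain": (0.0, 1.0),
}


@dataclass
class SessionConfig:
    """Validated bundle of every tunable the pipeline exposes."""

    camera: PinholeCamera = field(default_factory=PinholeCamera)
    tolerance_mm: float = DEFAULT_TOLERANCE_MM
    perfect_visibility: float = 0.9
    sweep: SweepSpec = field(default_factory=SweepSpec)
    novice: NoviceModel = field(default_factory=NoviceModel)
    drift: DriftModel = field(default_factory=DriftModel)
    seed: int = 0

    _KNOWN = {"camera", "tolerance_mm", "perfect_visibility", "sweep", "novice", "drift", "seed"}

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml

            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
        if not isinstance(obj, dict):
            raise SessionFormatError(f"{p}: config must be a mapping")
        unknown = set(obj) - cls._KNOWN
        if unknown:
            raise SessionFormatError(f"{p}: unknown config keys {sorted(unknown)}")
        kwargs = {}
        try:
            if "camera" in obj:
                kwargs["camera"] = PinholeCamera.from_json(obj["camera"])
            if "sweep" in obj:
                kwargs["sweep"] = SweepSpec.from_json(obj["sweep"])
            if "novice" in obj:
                kwargs["novice"] = NoviceModel(**obj["novice"])
            if "drift" in obj:
                kwargs["drift"] = DriftModel(**obj["drift"])
        except (TypeError, ValueError, KeyError) as exc:
            raise SessionFormatError(f"{p}: {exc}") from exc
        for key in ("tolerance_mm", "perfect_visibility", "seed"):
            if key in obj:
                kwargs[key] = obj[key]
        cfg = cls(**kwargs)
        cfg.validate(where=str(p))
        return cfg

    def validate(self, where: str = "config") -> None:
        for key, (lo, hi) in _RANGES.items():
            val = getattr(self, key, None)
            if val is None:
                val = getattr(self.novice, key, None)
            if val is None:
                val = getattr(self.drift, key, None)
            if val is None:
                continue
            if not lo <= float(val) <= hi:
                raise SessionFormatError(
                    f"{where}: field {key!r} = {val} outside allowed range [{lo}, {hi}]"
                )
        if not isinstance(self.seed, int) or self.seed < 0:
            raise SessionFormatError(f"{where}: field 'seed' must be a non-negative integer")

    @property
    def thresholds(self) -> ScoreThresholds:
        return ScoreThresholds(self.perfect_visibility)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(
            {
                "camera": self.camera.to_json(),
                "tolerance_mm": self.tolerance_mm,
                "perfect_visibility": self.perfect_visibility,
                "sweep": self.sweep.to_json(),
                "novice": asdict(self.novice),
                "drift": asdict(self.drift),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
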