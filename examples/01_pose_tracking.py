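"""Track two cube fiducials with a synthetic camera and recover their relative pose.

The core trick of camera-guided probe placement: the probe pose expressed in
the body-mounted reference-cube frame does not depend on where the camera
stands.  This script projects both cubes through a pinhole camera, estimates
each pose from the detected corners, and shows (a) a machine-precision
noiseless round trip and (b) sub-millimetre relative-pose errors under
realistic 0.5 px corner noise — from two different camera placements.
"""

import numpy as np

from echoguide import (
    CubeModel,
    PinholeCamera,
    Pose,
    compose,
    pose_error,
    relative_pose,
    track_frame,
)

camera = PinholeCamera(fx=800, fy=800, cx=320, cy=240, width=640, height=480)
cube = CubeModel(edge_length_mm=40.0)

# reference cube on the sternum, probe cube ~13 cm to its right, both ~0.5 m away
ref = Pose(np.array([1.0, 0, 0, 0]), (-60, 0, 500), "camera", "reference_cube")
probe = Pose.from_axis_angle((0, 1, 0), 15, (70, 10, 520), "camera", "probe_cube")
truth = relative_pose(ref, probe)
print(f"ground-truth relative pose: t = {truth.t.round(2)} mm")

status, rel = track_frame(camera, ref, probe, cube, noise_sigma_px=0.0, rng=0)
err = pose_error(truth, rel)
print(f"noiseless tracking error:   {err.translation_mm:.2e} mm, {err.rotation_deg:.2e} deg")

for label, motion in {
    "camera placement A": Pose.identity("camera", "camera"),
    "camera placement B": Pose.from_axis_angle((0, 1, 0), 8, (-50, 25, 60), "camera", "camera"),
}.items():
    rng = np.random.default_rng(42)
    errs = []
    for _ in range(100):
        _, rel = track_frame(
            camera, compose(motion, ref), compose(motion, probe), cube, 0.5, rng
        )
        if rel is not None:
            errs.append(pose_error(truth, rel).translation_mm)
    print(f"{label}: median relative-pose error {np.median(errs):.3f} mm "
          f"({len(errs)} tracked frames, 0.5 px corner noise)")

print("\nThe two medians agree closely: moving the camera does not change the")
print("probe-in-body-frame measurement, which is what makes saved probe poses")
print("reproducible days later with the camera on a different articulated arm.")
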