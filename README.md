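# echoguide

Simulation toolkit for **camera-guided ultrasound probe placement**: an expert
saves the probe pose that yields the diagnostic view of an organ, expressed
relative to a body-mounted fiducial, and a novice later reproduces that pose
on their own by aligning four virtual markers — with a motorized 3D fan sweep
as the fallback when the guided 2D view is incomplete.

The intended users are researchers studying remotely supervised or autonomous
ultrasound (spaceflight medicine, isolated sites, tele-echography) who need a
fully synthetic, reproducible testbed for this guidance protocol: every stage —
camera, fiducial tracker, body, operator, scoring — is simulated, so protocol
variants and error budgets can be explored without hardware or participants.

## The method

Two cube fiducials are tracked by a pinhole camera: a **reference cube** fixed
on the sternum (defining the body frame) and a **probe cube** on the
ultrasound probe. With camera-frame poses `T_cam←ref` and `T_cam←probe`
estimated from the cubes' corners (DLT initialization + Levenberg–Marquardt on
the reprojection error), the quantity the method records is the relative pose

```
T_ref←probe = T_cam←ref⁻¹ ∘ T_cam←probe
```

which is invariant to any rigid motion of the camera — the property that makes
a pose saved on day 1 reproducible on day 2 with the camera somewhere else.

**Acquisition.** The expert stores `T_ref←probe` for each of eight organ
targets (carotid, femoral, LV long-axis, four-chamber, cerebral, portal vein,
aorta, kidney) at the pose giving the ideal view.

**Restitution.** Four marker points rigidly attached to the probe cube (a
40 mm square) are compared against their saved positions. A marker turns
green when within a tolerance `t` (default 5 mm); when all four are green the
pose is *locked*. The four distances jointly bound the pose error: locked
implies translation error ≤ `t` and rotation error ≤ `2·asin(t / (2·r_eff))`
with `r_eff` = 20 mm the layout's worst-case lever arm (≈ 14.4° at default
tolerance) — verified by brute force in the test suite.

**3D rescue.** If the guided 2D view is incomplete, a fan sweep (default ±30°,
60 frames, tilt about the probe's lateral axis) is captured, compounded into a
voxel volume by reverse mapping, and resliced on oblique planes after the
fact to recover the diagnostic view.

**Evaluation.** Scans are scored 5 (complete direct view, Doppler-capable),
3 (partial direct view rescued by the 3D reslice), 1 (window found, nothing
usable), 0 (no organ visible), and aggregated into the percentages of windows
found, directly usable views, acceptable views and insufficient scans.

The synthetic layer reproduces the study's physical imperfections: Gaussian
corner-detection noise (0.5 px), reference-cube re-mounting error (uniform in
a 10 mm ball plus a ~2.5° twist of the support), respiration (2 mm sinusoid),
per-participant anatomical jitter, and per-organ acoustic-window cones (5°
for the transcranial window, 20–30° elsewhere).

## Worked example

```python
>>> from echoguide import run_study, aggregate
>>> table = run_study(n_participants=6, seed=42)      # 48 guided scans
>>> s = aggregate(table)
>>> s.pct_aw_found, s.pct_direct_usable, s.pct_acceptable
(81, 58, 81)
>>> sorted(s.mean_score_per_organ.items(), key=lambda kv: kv[1])[:3]
[('femoral', 1.5), ('carotid', 2.2), ('cerebral', 2.5)]
```

81% of acoustic windows were found, 58% of scans produced a directly usable
view, and including the sweep rescue 81% were acceptable; the thin superficial
vessels and the narrow cerebral window rank lowest. The `examples/` directory
contains one narrative script per capability (tracking, guided alignment,
sweep rescue, full study) — each prints its numbers with an explanation.

A thin CLI mirrors the pipeline:

```bash
echoguide acquire --seed 1 --out targets.json
echoguide restitute --targets targets.json --organ aorta --seed 2
echoguide simulate-study --participants 10 --exclude 1 --seed 7 --out study.csv
```

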