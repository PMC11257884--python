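# Methods

This note documents the models behind `echoguide`, the defaults and why they
were chosen, what the synthetic layer does and does not emulate, and the
numerical choices that matter. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`.

## Frames and conventions

Right-handed coordinates, millimetres and degrees throughout. The **camera
frame** follows the computer-vision convention (+z optical axis, +x right,
+y down). The **body frame** has its origin at the sternum mount of the
reference cube, +x toward the participant's left, +y toward the feet, +z into
the body. The **probe frame** has +z along the beam (into the body), +x
lateral; the image plane is the probe's x–z plane, so the plane normal (+y)
is the elevation direction. Poses are unit quaternions (scalar-first, scalar
canonicalized non-negative so the representation is unique) plus a
translation, and carry explicit parent/child frame labels that every
composition checks — frame mixups are the dominant bug class in this kind of
pipeline, and the method's correctness rests on one specific frame
expression (probe-in-reference-cube).

Rotation angles between poses are computed with the chord form
`4·asin(‖qa ∓ qb‖/2)` rather than `2·acos(|⟨qa,qb⟩|)`; the latter loses half
the available digits near zero and cannot support the 1e-9 identities the
geometry layer guarantees.

## Fiducial tracking

The tracker is a functional stand-in for a commercial multi-target SDK, not a
replica. Correspondence primitives are the eight cube corners (edge 40 mm)
rather than textured faces: at desk scale they give the same 6-DOF
observability without implementing feature detection. Projection is an ideal
pinhole (no distortion, no rolling shutter); corner noise is isotropic
Gaussian with σ = 0.5 px by default, a standard corner-detector error model.

Pose estimation minimizes summed squared reprojection error: a DLT
initialization (from ≥ 6 corners) followed by Levenberg–Marquardt to machine
tolerance; with only 4–5 visible corners the initialization is a multi-start
over the cube's 24-element rotation group at a depth guessed from the
projected corner spread. There is no RANSAC because the simulation produces
no outliers. A cube with fewer than four visible corners (or corners
collinear in the image) is *untrackable* — an ordinary output driving the
tracking-status display, not an exception. Noiseless round trips recover the
generating pose to better than 1e-6 mm/deg (checked over 1000 random poses),
and the estimator's reported RMS never exceeds the ground-truth pose's RMS on
the same detections.

## Marker alignment and the lock bound

The four guidance markers are the corners of a 40 mm square **centred on the
probe-cube origin**, parallel to the cube's top face. Centring the layout's
centroid exactly at the origin makes the first half of the lock guarantee
exact: the mean marker displacement equals the translation error, so locked
(all four distances ≤ t) implies translation error ≤ t.

For rotation, the relevant lever arm is *not* the marker-to-centroid radius
(28.3 mm): a rotation about an axis parallel to a square edge moves every
marker by only `2·(s/2)·sin(θ/2)` with `s/2 = 20 mm` the half side. The
implemented bound is therefore `θ ≤ 2·asin(t / (2·r_eff))` with `r_eff` the
minimum over axes through the centroid of the largest marker distance to the
axis (20 mm for the default layout, computed numerically with the layout's
principal and edge directions included as exact candidates). The bound is
guaranteed for centrally symmetric layouts, which the default is; the test
suite verifies it by brute force over 10,000 random offsets. At the default
5 mm tolerance the bound is 14.36°.

The 5 mm tolerance itself is a design choice: the original system's threshold
is unknown, but the reference-cube support repositions the cube only to
within ~10 mm between sessions, so a same-order value is the natural scale.
All study-level conclusions are checked as orderings, never against this
absolute.

HMI instructions are computed in the reference-cube (body) frame — "move
left" must be body-relative, not camera-relative, to be reproducible — by
taking the dominant axis of the translation error, with a tilt hint appended
when the rotation error exceeds 5°.

## Body phantom and image formation

The phantom is a voxel grid (default 2 mm spacing, 300 × 390 × 150 mm) of
echogenicity in [0, 1]: background 0.3 with smooth low-frequency texture
(±0.05), plus eight axis-aligned ellipsoidal organ analogs at
anatomy-inspired offsets from the sternum — superficial vessels thin and
shallow, cardiac targets left-thoracic, abdominal organs deep, a small
spherical transcranial target. Organ centres, sizes and echogenicities are
plausible rather than measured; no study-level guarantee depends on their
exact values.

B-mode formation is deliberately first-order: trilinear sampling of
echogenicity on the image plane, multiplied by depth attenuation
`exp(−μ·z)` with μ = 0.005 /mm (≈ 4.3 dB at 100 mm, a soft-tissue order of
magnitude), optionally multiplied by Rayleigh speckle with unit mean
(mean-preserving, so visibility logic is noise-robust). No wave propagation,
refraction, true shadowing or deformation is modelled.

**Acoustic windows** are geometric: each organ carries a cone of half-angle
`a` (5° cerebral; 20° superficial and cardiac; 30° abdominal) about its
best-view axis, with the apex anchored at the organ centre. Insonation
succeeds only if both the beam direction and the bearing from the probe's
skin entry point to the organ centre lie inside the cone. Anchoring the cone
at the organ is what makes a *narrow* window punish position as well as
orientation errors — a 5° cone over a 60 mm-deep target tolerates only
~5 mm of entry-point offset — reproducing the clinical fact that the temporal
bone window fails under minor placement errors while wide abdominal windows
tolerate centimetres. Outside the cone the organ renders at 10% contrast
(a bone-shadow proxy) and counts as invisible.

**Visibility** of an organ in a plane is the area of the organ's label region
intersected by the (frame-clipped) plane divided by the area at the organ's
expert pose, precomputed per organ at phantom build; the aperture gate forces
zero. The expert pose — probe on the skin above the organ centre, beam along
the best-view axis, image plane containing the organ's long axis — maximizes
visibility by construction, which makes "expert acquisition" well defined in
simulation.

The default frame is 100 mm wide × 140 mm deep at 1 mm pitch. The width
barely contains the longest organ views (the aorta's long axis), exactly as
clinical long-axis imaging does; this is what produces the characteristic
failure of a guided-but-offset placement — organ clipped or missed in the
direct view, recoverable (or not) from the sweep.

## Fan sweep and reconstruction

The 3D capture is a motorized fan: the image plane tilts about the probe's
lateral axis from −θ to +θ (default θ = 30°, 60 frames; both configurable,
since the original capture geometry is unpublished). Reconstruction is
voxel-driven reverse mapping on a grid aligned with the base probe frame:
each voxel finds its nearest frame plane analytically (the fan geometry makes
this a single angle computation), and if the perpendicular distance is within
one voxel it bilinearly samples that frame at the foot point. Voxels inside
the wedge but beyond the threshold get the average of the two bracketing
frames' samples and are flagged *interpolated*; everything else is a hole.
Reverse mapping avoids the bin-filling artifacts of forward splatting and is
directly checkable against trilinear samples of the source phantom: a dense
noiseless sweep agrees with direct phantom sampling to ≤ 0.02 mean absolute
intensity, and reslicing the volume at a captured frame's pose reproduces
that frame to the same tolerance (measured ≈ 2×10⁻⁴ in practice).

Oblique reslicing is plain trilinear sampling with a validity mask (observed
or interpolated voxels only); no smoothing, so results can be checked against
closed-form samples. The best-plane search is an exhaustive grid over tilts
spanning the wedge. Doppler and time-motion are *not* available from the
reconstructed volume — they require live acquisition — and are represented
only as capability flags.

## Simulated study

The study runner mirrors a two-day protocol with 8 organs per participant.
Day 1 (acquisition) stores each organ's expert pose relative to the reference
cube. Day 2 (restitution) perturbs the world in three ways:

- **placement error**: the cube is re-mounted with a translation uniform in a
  10 mm ball (the support structure's stated repeatability) *and* a small
  twist, Gaussian 2.5° about a random axis. The twist matters through its
  lever arm — organs sit 100–200 mm from the sternum, so 2–3° displaces a
  distal target by 5–10 mm even when the cube-relative pose is reproduced
  exactly. A support strapped to soft tissue between sessions, with the
  body in a slightly different position, realistically moves by this much;
- **respiration**: a 2 mm, 4 s sinusoid along the anterior–posterior axis,
  applied to the cube continuously while the novice aligns;
- **anatomy jitter**: per-participant organ centres perturbed by Gaussian
  σ = 8 mm, creating inter-participant variation without external data.

The simulated novice starts at the saved pose plus a random offset
(σ = 15 mm / 10°, the scale of an initial hand placement after coarse visual
guidance) and each step closes half of the currently *estimated* pose error
(translation toward the target, rotation along the geodesic), stopping at
lock or 40 steps at 2 Hz. Closing a fixed fraction per step is the simplest
model of a human servoing on a proportional visual cue; because lock fires at
the first step under tolerance, residual errors at lock sit just below the
threshold rather than far below it, as with a real operator who stops as soon
as everything turns green.

The final scan is scored from the direct-view visibility and the best
visibility over oblique planes within the sweep wedge, with "complete view"
operationalized as ≥ 0.9 of the organ's reference cross-section (the original
judgment was human; 0.9 is a proxy, configurable, and no conclusion is tied
to its absolute value). For cardiac targets the published rubric ties score 5
to live Doppler/time-motion capability, which only the direct view has — this
is operationally identical to the general rule and is implemented as such.
"Insufficient" is the complement of "acceptable" (scores 1 and 0 over the
same denominator), which is the only reading under which the published count
table (73 found / 32 direct / 67 acceptable / 12 insufficient of 79) is
internally consistent: it decomposes as 32/35/6/6 by score.

Percentages round half away from zero, the convention that reproduces all
four published pairs (92/41/85/15).

**Problem sizes.** The acceptance run uses 200 scans (25 participants × 8
organs) with 2.5 mm phantoms; the published study had 79. The package's other
guarantees use 1000 poses (round trip), 10,000 offsets (lock bound) and a
60-frame sweep at 1 mm voxels — sizes at which each check is stable and the
whole suite completes in about a minute.

## What passing tests do and do not show

The synthetic layer emulates the *geometry* of the problem faithfully —
frame relationships, tracking noise propagation, marker-lock guarantees,
wedge coverage, window cones — so passing tests validate the protocol's
geometric logic and its failure modes (placement drift losing narrow windows,
the sweep rescuing elevation misses but not in-plane clipping). It does not
emulate image *quality*: speckle statistics beyond first order, contrast
loss, operator fatigue, or the human judgment behind "usable for diagnosis".
Simulated percentages therefore reproduce the qualitative structure of a real
study (found ≥ acceptable > direct; cerebral lowest) but not its exact
numbers, and nothing here validates performance on real ultrasound data.
Found-but-unusable outcomes (score 1) in particular are rarer in this
geometric world (~1–2% of scans) than in human scoring, where image-quality
judgments produced them at ~8%.

## Known limitations

- The cube tracker is corner-based; real multi-face texture tracking has
  different (pose-dependent) error anisotropy.
- Ellipsoidal organs with hard aperture cones; no ribs, gas, or refraction.
- The fan sweep assumes a motorized, exactly repeatable tilt; freehand
  trajectories and probe-holding drift during capture are not modelled.
- The novice model has no memory, fatigue, or overshoot; convergence is
  geometric by construction at gain < 1.
- NIfTI is used for volumes and phantoms (spacing/origin in the header);
  the NRRD container is not supported.
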