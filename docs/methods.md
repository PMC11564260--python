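# Methods

This note documents the model behind ffmkit, its assumptions, the
parameters that matter, and the choices made where the procedure was
genuinely open. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute themselves.

## Model and procedure

The fossa-foveolar mismatch (FFM) index quantifies, for one motion
protocol, the fraction of the fovea capitis' motion-tracking surface that
lies outside the acetabular fossa, measured in a standardized medial 2D
projection. The pipeline is:

1. **Standardized frame.** The acetabular center and radius come from an
   algebraic least-squares sphere fit over LUNATE-labeled vertices, the
   femoral head center from the same fit over HEAD vertices (FOVEA and
   OTHER excluded, so a cam bump cannot bias it). The mediolateral axis is
   the direction from the acetabular center to the lunate centroid. The
   remaining degree of freedom — roll about that axis — is fixed by
   rotating the pelvis until the vector from the fossa centroid to the
   transverse-ligament origin landmark points straight inferior in the
   medial view. "Horizontal alignment" of that landmark is not defined
   quantitatively in the clinical literature this emulates; the roll
   construction is our assumption, chosen because it fixes exactly the
   degree of freedom a reproducible medial view needs and is the identity
   on canonically generated synthetic hips. The femur is translated so the
   fitted head center coincides with the acetabular center. Everything
   downstream is therefore invariant to rigid pre-transforms of the input
   pair (asserted to |ΔFFM| ≤ 1e-3 in the tests), and the construction is
   idempotent. Canonical axes (right hip): +x anterior, +y medial,
   +z cranial; left hips are mirrored across the sagittal plane at load
   time.

2. **Pose grids.** Each of the 17 protocols is a set of branches: a fixed
   pre-rotation plus one swept elementary motion in 10° steps from neutral
   outward. A pose's rotation is the intrinsic sequence flexion (about
   −y) → abduction (about −x) → axial rotation (about +z, internal
   positive); the source procedure's software convention is unknown, so
   this is a stated package convention used consistently by pipeline and
   oracle alike. Default ROM limits (flexion 120°, extension 20°,
   abduction 50°, adduction 30°, IR 30°, ER 40°, the same rotations at 90°
   flexion; anterior impingement test = 90° flexion + 10° adduction + IR
   0–30°; posterior = 10° extension + ER 0–40°) are calibrated so the
   standard pose counts hold (15 poses for combined flexion/extension, 4
   for the anterior impingement test); they are configuration, not
   population measurements. "Total ROM" is not a new sweep: it is the
   union of all admissible poses of the other 16 protocols.

3. **Impingement truncation.** At each pose the femur-pelvis pair is
   tested for triangle-triangle intersection (tolerance 0 mm by default;
   a positive tolerance switches to a minimum-distance test, exposed for
   sensitivity studies). Branches are truncated independently at the first
   colliding step. Face pairs labeled {HEAD, LUNATE} are excluded: the
   articulating surfaces are permanently in near-contact and their
   proximity is not impingement; all other pairs (cam bump, rim, fossa and
   fovea edges) count. If the anatomical neutral itself collides the
   geometry or clearance is invalid and the run aborts. An impingement-test
   branch whose fixed starting pose collides truncates to empty; a protocol
   left with no admissible pose falls back to the anatomical-neutral
   footprint so its pattern is never empty.

4. **Tracking and index.** The fovea is characterized once in neutral as a
   spherical disc: center = normalized mean of FOVEA vertex directions
   about the hip center, angular radius = smallest angle containing all
   FOVEA vertices. At each pose the disc is rotated rigidly and mapped
   radially onto the acetabular sphere — a disc, not a re-meshed contact
   patch, because rigid motion preserves it exactly and it keeps the
   analytic oracle exact. Footprints and the fossa boundary loop are
   projected orthographically along the mediolateral axis; regions are
   clipped to the hemisphere facing the acetabulum (y ≥ 0) first, because
   the orthographic map folds once an end-range pose carries the disc past
   the equator. The per-protocol pattern is the exact polygon-boolean union
   (shapely) of the footprints, partitioned by the projected fossa
   boundary; FFM = outside area / total area. The index is deliberately a
   2D projected quantity — mirroring the method it implements, which
   accepts the known limitation of quantifying a 3D problem in a 2D view —
   while true spherical areas are additionally available
   (`TrackingPattern.spherical_area_total`) for research use. Combined
   protocols union the footprints of both branches rather than averaging
   branch indices.

## Synthetic data and what a green test establishes

`generate_hip` emits an idealized hip: the femoral head is an exact sphere
meshed as a polar grid centered on the fovea axis (so the FOVEA boundary is
a vertex ring at exactly the requested angular radius), the acetabulum is a
concentric spherical shell band (lunate) with a fossa cap separated by an
exact ring, joint space is a uniform `clearance`, and a short neck/shaft
stub allows extra-articular contact. Defaults: head radius 24 mm, fovea
disc 14°, fossa cap 30°, lunate coverage 70°, clearance 0.5 mm (so neutral
never collides), target edge length 1.5 mm — values a clinician would call
an unremarkable adult hip; the fovea is concentric with the fossa by
default and displaced explicitly in experiments. The optional cam bump is a
radial Gaussian at the head-neck junction whose amplitude/extent map only
qualitatively to alpha-angle severity. The generator is fully parametric
and therefore deterministic; the seed is metadata.

`analytic_ffm` is the independent oracle: dense rasterization in the
medial-view plane, each pixel lifted to the near hemisphere of the
acetabular sphere and tested against the rotated fovea discs and the fossa
cap analytically. It shares the projection convention but none of the mesh
pipeline's code. Pipeline-oracle agreement (within 0.02 across a sweep of
fovea offsets 0–40° and fossa radii 15–35°; in practice well under 0.005 at
default resolutions) establishes that meshing, frame recovery, boundary
extraction and polygon booleans are faithful — it does *not* establish
realism of the geometry: real acetabula are aspherical, joint space is
nonuniform, fossa margins are irregular, and soft tissues (ignored here,
as in the source method) can reduce simulated ROM substantially. Absolute
FFM values on synthetic hips are not comparable to patient values.

The rating-table generator draws the two-way random-effects model
y = μ + subject + rater + residual (effects shared across sessions,
independent per motion), which is exactly the model under which the ICC
estimator is derived — recovery tests (population ICC 0.9 recovered within
0.03, CI coverage ≈ 95%) validate the estimator, not the behavior of human
raters.

## Reliability statistics

`icc_agreement` computes ICC(A,1) — two-way random effects, absolute
agreement, single measurement — from the ANOVA mean squares, with the
McGraw–Wong F-based 95% CI (Satterthwaite degrees of freedom). The source
procedure reports ICCs without naming the variant; ICC(A,1) is the default
here because raters and sessions are both exchangeable random facets in
this design, and pingouin's independent implementation is used as a
cross-check in the tests. Qualitative labels: > 0.75 excellent (strict),
0.6–0.75 good, 0.4–0.6 fair, < 0.4 poor; the boundaries 0.75 and 0.6
classify as good and 0.4 as fair. Negative estimates are reported as
computed, not floored. Zero-variance input raises instead of returning
NaN. The report layout is one intraobserver ICC per rater (sessions as
columns) and one interobserver ICC per session (raters as columns), per
motion.

## Numerical choices

- Sphere fits are algebraic linear least squares; no full-coverage
  requirement (a cap suffices), residual thresholds default to 1.5 mm rms.
- Projected disc boundaries use 90 segments (inscribed-polygon area error
  ≈ 0.08% at that count); the fossa outline uses the actual mesh boundary
  loop. The raster fallback backend defaults to 0.1 mm and agrees with the
  polygon backend within 2 · resolution · perimeter.
- Collision narrow phase: segment-through-triangle tests (Möller–Trumbore,
  inclusive boundaries) on both triangles' edges plus a coplanar
  separating-axis fallback; broad phase: KD-tree over triangle centroids
  with conservative circumradius bounds, so the accelerated result equals
  exhaustive all-pairs testing (asserted on random pairs).
- The oracle's default grid (400 pixels across the pattern) converges to
  ≈ 1e-3 against an independent polar-coordinate integration.
- FFM values are clamped only within ±1e-9 of the [0, 1] boundaries to
  absorb float round-off; anything further out raises.
- Degenerate inputs raise typed errors (`ConfigError`, `DataError`,
  `NumericalError`) that the CLI maps to exit codes 2/3/4.

## Known limitations

- Pure ball-joint kinematics: no translation, no cartilage deformation, no
  soft-tissue constraint on ROM.
- The fovea is tracked as a rigid disc; an irregular fovea margin is
  represented only through its enclosing angular radius.
- The medial-view index inherits the 2D-projection bias of the method it
  implements; patterns are comparable across morphologies only because the
  projection convention is identical for all cases.
- The synthetic acetabulum is a spherical band, not a hemipelvis; collision
  against structures far from the joint (e.g. anterior inferior iliac
  spine) is out of scope.
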