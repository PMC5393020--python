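# Methods

This note documents the model, its assumptions, the constants that matter,
and what the synthetic cohort can and cannot show.  Units are mm, N, N·mm
and degrees throughout; the global frame is right-handed with X anterior,
Y to the patient's left, Z cephalad.

## Synthetic spine geometry

The generator replaces radiographic 3-D reconstruction.  Vertebral body
dimensions come from a shipped anthropometric table (monotone from T1 to
L5) scaled linearly with stature; each vertebra carries endplate
centers/corners, pedicle entry points, transverse and spinous process
landmarks, plus derived soft-tissue attachment points.

Vertebral centers follow a curve obtained by integrating two tilt
profiles: a coronal profile interpolated (monotone piecewise-cubic)
through end-vertebra controls of the three regional arcs — the signed tilt
difference across each region equals its requested Cobb angle, and the
tilt crosses zero at each apex so the apex is the laterally extreme
vertebra — and an analogous sagittal profile for kyphosis (measured T2–T12
by default) and lordosis (L1–S1, the pelvic sacral plate standing in for
S1).  Axial rotation follows a cosine bump peaking at each curve apex with
amplitude equal to the apical vertebral rotation.  Because plane
projections couple, a deterministic fixed-point loop re-measures the
geometry and adjusts the control amplitudes until every index lands within
0.2° (0.5° for rotations), well inside the advertised ±1°/±2° contract.

Convexity is not printed in case tables; the default makes the main
thoracic curve convex right and its neighbors convex left (the typical
right-thoracic pattern), configurable per case.  The whole assembly is
rigidly rotated so the pelvis lies on the T1 plumb line in both planes
(a compensated, balanced trunk).  The per-case seed perturbs only
mirror-symmetric features (sagittal profile, dimensions), so generation is
deterministic and flipping the convexity produces the exact mirror image.

## Multibody spine model

Vertebrae and pelvis are rigid bodies.  Each FSU carries

* six tension-only cables (anterior/posterior longitudinal ligaments,
  ligamentum flavum, left/right intertransverse, interspinous+supraspinous
  combined).  Traction stiffnesses at T6–T7 are the cadaveric values
  23.6 / 24.9 / 32.6 / 12.9 / 32.1 N/mm, scaled at other levels by the
  vertebral-body depth ratio (a cross-section proxy); compressive force is
  exactly zero,
* two facet-capsule 6-D diagonal springs, and
* one primary 6-D disc spring acting at the disc center, which also
  absorbs everything not explicitly modeled (notably the rib cage, whose
  weighting stiffens thoracic FSUs by ×1.40 / ×1.35 / ×1.31 in
  flexion-extension / lateral bending / axial rotation).

All elements are assembled force-free in the preoperative geometry: the
deformity is the elastic rest state, and correction therefore requires
permanently held forces, which the locked construct supplies.

### FSU-level calibration

Per-mode stiffness targets for the reference unit are not published; the
shipped defaults represent a relaxed intraoperative spine — flexion 2000,
lateral bending 800, axial rotation 1200 N·mm/deg, axial compression
1000 N/mm, shear 1500 N/mm at T6–T7, scaled by depth ratio elsewhere —
and are ordinary configuration (`calibration.REFERENCE_MODE_TARGETS`).
They were chosen once, jointly with the attachment lever arms, under two
constraints: the printed surgical-release reductions must be *feasible*
(the removable elements, whose ligament stiffnesses are fixed by the
printed values, must not already exceed the removable share in any mode),
and the calibrated models must behave like anesthetized scoliotic spines
rather than awake cadaveric specimens.  A small-displacement
displacement-controlled probe (0.5° / 0.5 mm) defines FSU stiffness; the
calibrator fits the disc diagonal so every probe hits its target (within
2 %), then apportions the facet diagonals — and, only when a mode's
removable share is otherwise infeasible, shrinks the interspinous cable —
so that applying the surgical release reduces each mode by exactly 17 %
(axial rotation), 15 % (flexion), 3.8 % (coronal bending) and 14 % (axial
compression), to 0.1 percentage points.  The rib-cage factors multiply the
calibration target of thoracic units and are absorbed by the disc
diagonal, so the *assembled unit* stiffens by exactly the printed ratios.
Calibration uses canonical straight-spine units at reference stature;
patient-specific lever deviations are absorbed by the patient-level stage.

### Patient-level (flexibility) calibration

Side bending is simulated with the pelvis fixed and a gentle pure coronal
moment (0.6 N·m at T1 plus 0.05 N·m per vertebra, shared across cases so
that stiffness, not load, absorbs inter-case variation).  This load
constant pins the absolute calibrated stiffness scale — stiffness equals
load over observed deflection — and with it the magnitude of the
simulated implant forces.

Measured bending pairs are strongly asymmetric (case 1's main thoracic
curve moves 26° toward correction but only 4° the other way), which no
single symmetric factor can fit.  Each curve region therefore carries one
scale factor per bending direction (six factors, bounds [0.1, 10], fixed
initial guess 1, log-space secant updates; deterministic).  The factors
represent coronal-plane flexibility and accordingly multiply only the
coronal rotational stiffness and the ligament cables; sagittal and axial
rotational terms and all translational disc/facet stiffnesses remain at
their anatomical calibration.  Correction simulations use each region's
corrective-direction factor (bending toward a curve's convexity
straightens it).  All six bending Cobb targets are met within 0.5°
(contract: 2°), and randomized truth-recovery experiments recover
generating factors with median relative error below 10 %.

## Instrumentation and the maneuver

Screw patterns: bilateral reference; alternate dropouts start one level
caudal to the upper instrumented vertebra and may land on the lowest one
(the upper always keeps both screws); periapical dropouts remove the same
number of consecutive screws centered on the apex.  On the shipped cohort
this yields reductions of 22.7–25 % with mean 23 %.  Thoracic screws are
5.0 mm, lumbar 5.5 mm; rods are 5.5 mm cobalt-chrome (E = 230 GPa),
contoured 25° (convex side) / 35° (concave) over the thoracic segment
with a 20° lumbar counter-bend, discretized as rigid nodes joined by
slender-beam 6-D springs (EA/L, EI/L, GJ/L; translational entries capped
at 2·10⁴ N/mm for conditioning — rod axial/shear compliance is
irrelevant here).

The screw-rod connection is the load-bearing abstraction of a polyaxial,
dorsal-height-adjustable implant: the constraint is the distance from the
ball joint (3 mm dorsal of the pedicle entry) to the rod axis, ramped from
the initial gap to the 15 mm locked head standoff at a common rate across
screws.  The approach direction is force-free within a 25° polyaxial cone
about the shank axis and clamped at the cone boundary, so angulation
absorbs medio-lateral misfit over its physical range only; the rod slides
freely through the saddles (the most cephalad screw of each rod pins the
rod's axial seating).  Each screw locks rigidly — translations and
rotations frozen, transmitted force continuous — as soon as it seats
(within 0.5 mm of its commanded distance); remaining screws lock at the
end of the 20-step schedule, the connections stiffen from 800 to
3000 N/mm, and the final locked equilibrium is solved at the strict
tolerances.  Locking progressively *during* translation is deliberate: a
point connection transmits no moment, so an end-only lock would leave
vertebral orientations (hence measured Cobb, kyphosis and rotation)
largely uncorrected; the hardware's ability to "lock at any point of the
correction" is what transfers moments as the maneuver proceeds.  Boundary
conditions: pelvis fully fixed, T1 transverse translations constrained
(both config-overridable).  Gravity and positioning loads are excluded
(config toggle).

Bone-screw force is the translational reaction transmitted at each anchor
in the final locked state; cohort statistics pool all screws of all cases
per pattern.  Pattern comparisons use a Welch two-sample t-test on the
pooled per-screw forces (primary; pooled min–max reporting suggests
per-screw pooling) with a paired t-test on per-case means as sensitivity
output; raw and Holm-adjusted p-values are both reported.

## Numerical methods

Equilibrium of the rigid bodies (6 generalized coordinates each; rotation
vectors re-linearized every iteration) is found by damped Newton iteration
with adaptive Levenberg-style regularization and a finite-difference
Jacobian fallback when the analytic tangent stalls.  Element generalized
forces are variationally exact (the residual is the exact negative
gradient of the elastic energy; verified against numerical gradients),
which guarantees exact action-reaction and rules out spurious
non-conservative cycles.  The tension-only cable law carries a 0.1 mm C¹
blend just above the rest length: force remains exactly zero at and below
rest, the deviation from the ideal kinked law stays below the 0.5 N
residual tolerance, and Newton no longer stalls when many ligaments sit at
the slack onset.  Loads are applied over increments with automatic
halving; the displacement-driven maneuver bisects its ramp fraction
instead.  Convergence means force residuals ≤ 0.5 N and torque residuals
≤ 50 N·mm on free degrees of freedom, re-verified by direct residual
evaluation.  Everything is deterministic; the only randomness in the
package is the geometry generator's seeded jitter.

Problem sizes: a spine solve has 18 bodies (108 DOF); an instrumented
solve adds ~40 rod nodes (~350 DOF).  The full cohort (10 cases
calibrated, 50 correction simulations) runs in about three minutes on one
CPU with 20-step schedules, which is the default used by the tests and the
reproduction script.

## What the synthetic cohort does and does not show

The generator matches the *printed indices* of real cases, but the
underlying shapes are smooth parametric curves with statistically mild
per-vertebra irregularity; real reconstructions carry local wedging,
rotatory subluxation and sharper apical geometry.  Passing tests therefore
demonstrate that the pipeline reproduces the study's calibration
quantities and its qualitative mechanics on index-matched geometry — not
that it predicts any individual patient.

Two cohort-level claims are *not* reproduced at the published tightness,
and the suite reports them honestly rather than relaxing the check:

* **Pattern equivalence.**  The published corrected-index deviations
  between alternative and reference patterns (≤ 8° Cobb in the worst of
  40 simulations; ≤ 2° kyphosis/rotation) come out larger here (about
  18° and 8° in the worst cases).  The excess concentrates in short,
  angular curves (the same cases flagged as most force-sensitive in the
  source analysis) and in periapical dropout patterns, where this model's
  point-wise screw-rod connections leave more orientation freedom than
  the reference implementation apparently did.
* **Force ordering.**  With patterns pooled over the whole cohort, mean
  bone-screw force of the alternative patterns is not consistently above
  the reference pattern's here (alternate-level dropouts do exceed
  periapical ones, matching the published direction).  Absolute force
  levels are geometry- and stiffness-scale-dependent and are reported for
  comparison only.

Known limitations: no gravity or intraoperative positioning loads; no
viscoelasticity or stress relaxation (real curves relax during surgery);
the elastic rest state equals the preoperative geometry, so the model
cannot spring back on its own; facet contact is a linear spring, not a
unilateral contact; rods are sagittally planar; and the screw-rod
interface omits friction, modeling reduction as an idealized
displacement-driven persuader with progressive locking.
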