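# Methods

This note documents the models behind `kneevar`, the assumptions they
make, the numerical choices, and what the synthetic parts of the
pipeline can and cannot say about real knees.

## 1. Cartilage constitutive model

Cartilage is modelled as an exactly incompressible second-order Yeoh
solid, `W = C10 (I1 − 3) + C20 (I1 − 3)^2` (constants in MPa).
Incompressibility is enforced through the kinematics
(λ2 = λ3 = λ1^-1/2) rather than a nearly-incompressible penalty; for
short-time compressive loading of cartilage this is a standard and
well-supported simplification.  Anisotropy, strain-rate dependence and
poroelastic flow are out of scope — they would multiply the parameter
space that the uncertainty study is designed to sample.

Sign convention, used everywhere: compression is λ < 1 with negative
axial stress; contact pressure is the negated stress.  The small-strain
limit of the uniaxial response gives the incompressible Young's modulus
E = 6·C10, which the tests verify numerically.

Material uncertainty enters through the published mean ± 1 SD ranges of
the four constants (femoral/tibial × C10/C20) for healthy and
OA-affected condylar cartilage; the defaults in
`kneevar.sampling.MaterialRanges` are those ranges verbatim.

## 2. Foundation contact model

The condylar interface is a sphere (R = 40 mm) on a plane with two thin
cartilage layers (2.3 / 2.1 mm) and rigid bone backing — bone
compliance is known to be negligible at this interface, so the bone
modulus/Poisson fields of `ContactPairSpec` are documentation only.

Because the layers are ~20× thinner than the sphere radius, the pair is
solved as a nonlinear Winkler (elastic-foundation) model: each surface
point is an independent column of the two layers in series.  Two
choices deserve explanation:

* **Traction measure.**  An incompressible column widens by the area
  factor 1/λ as it shortens, so the force it transmits per unit
  *reference* patch area — the quantity integrated over the undeformed
  radial grid — is the nominal (first Piola-Kirchhoff) traction
  N = σ/λ, not the Cauchy stress itself.  Equivalently: the Cauchy
  stress acts on the column's current, widened cross-section.  Using σ
  directly would understate the transmitted force by ~20 % at 1 mm
  indentation.
* **Series coupling.**  The two layers share one traction; their
  stretches solve N_f(λ_f) = N_t(λ_t) with compressions summing to the
  local interpenetration.  The public `column_pressure` uses bracketed
  scalar root finding (Brent, tolerances 1e-12 on λ, 1e-10 MPa on p);
  the patch integral uses an equivalent vectorised two-variable Newton
  iteration across all radial nodes, cross-checked against the scalar
  solver and against a brute-force nested bisection oracle in the
  tests.

The patch integral uses the exact sphere profile (not the parabolic
approximation) on a fixed 400-node trapezoid grid; a 10×-finer grid
changes the force at 1 mm by well under 0.1 %.  At small indentation
the model converges to the linear elastic-foundation closed form
F = πRδ² / (t_f/E_f + t_t/E_t), which the tests check at δ = 0.01 mm.
Curves are solved at 20 equal steps to δ = 1.00 mm with an explicit
(0, 0) anchor point — 21 stored points — so that downstream piecewise-
linear evaluation has an exact origin; beyond the last point the curve
is extrapolated along its final segment (a dynamic simulation may
overshoot 1 mm transiently).  The validated indentation range ends at
1.05 mm; the solver refuses prescribed indentations beyond it.

What the foundation surrogate does *not* capture: lateral shear
coupling between columns and the confinement stiffening of thin bonded
incompressible layers under a wide contact patch.  Consequences for the
study: the force *levels* and the healthy-group dispersion agree well
with a full FE treatment of the same geometry, but the OA group —
whose ranges include very soft tibial samples — shows a smaller spread
(CV ≈ 23 % rather than ≈ 30 %) because the series compliance of two
independent columns damps the influence of the softest layer.  The
scale-free group orderings (healthy stiffer than OA, OA relatively more
variable) are robust to this.

## 3. Sobol designs

Both stages use unscrambled base-2 Sobol points with the origin
included, generated by `scipy.stats.qmc`; determinism was preferred
over scrambling because the study reports dispersion statistics, not
confidence intervals, and bit-identical repeatability is worth more
here than randomised error estimates.  The origin point maps to the
all-minima material corner, which is physically valid (the healthy
femoral C20 minimum is 0.0).  Stage-1 column order is
(femoral C10, femoral C20, tibial C10, tibial C20); stage-2 order is
(ACL, PCL, MCL, LCL) × (femoral, tibial) × (x, y) for the 16 offsets,
then the four stiffness multipliers.  Both orders are recorded in the
output manifests.  The same unit design is scaled to both tissue
groups, pairing the samples across groups — this is what makes the
healthy/OA comparisons per-sample rather than merely distributional.

## 4. Planar hybrid knee model

Frames and conventions: tibia fixed with its plateau along y = 0
(normal (0, 1)), x posterior, y up; the knee angle θ is 0° at full
extension and grows with flexion; femoral geometry is specified in the
femur frame at full extension and rotates clockwise (posterior roll)
with θ.  A positive external moment extends the knee, so the
generalized torque conjugate to θ is −M_ext.  Internally everything is
SI (m, N, rad, s); all interfaces use mm and degrees.

Forces on the femur: four tension-only cables with the standard
quadratic-toe/linear law (toe parameter 0.03, force and slope
continuous at strain 0.06); two condylar circles of radius 40 mm whose
penetration of the plateau is looked up in the per-sample
force–indentation curve (full curve per pair, no force splitting);
linear viscous damping on both velocities; no gravity — the protocol is
purely moment-driven.  Torques are assembled through the kinematic
Jacobian of each attachment point (virtual work), which the tests check
against a finite-difference statics oracle at 1e-9.

Dynamics: semi-implicit (symplectic) Euler — velocity first, position
with the new velocity — at dt = 1 ms for 16 s per branch.  The moment
rises in five equal increments (at t = 0, 3.2, 6.4, 9.6, 12.8 s) to
±3.5 Nm; "applied in five steps over 16 s" is interpreted as five equal
plateaus of 3.2 s each.  Equilibrium angles are recorded at each
plateau's end; a divergence guard (5 m/s, 50 rad/s) aborts a run with
the failing step.  With the chosen damping every plateau of every model
in the study settles: final kinetic energy below 1e-6 J and residual
generalized force below 1e-3 N (N·m) are asserted in the tests.

## 5. The synthetic nominal knee

The multibody stage follows a published planar architecture whose
numerical parameters are not publicly printed, so the nominal model is
a *calibrated synthetic stand-in* (`scripts/calibrate_knee.py`; frozen
constants in `kneevar.synthetic_knee`).  Every parameter carries a
provenance note ("printed" vs "synthetic") in `nominal_spec()`.  The
calibration targets are the documented behavioural anchors: neutral
equilibrium near 55° (achieved: 56.0°), motion range near 74° under
±3.5 Nm (achieved: 70.5° with healthy mid-range curves), an ACL that is
exactly silent in flexion, and plateau-wise settling.

The load-bearing design choices, found during calibration:

* **Cruciates as end stops.**  The ACL engages ~32° below neutral and
  stops extension through a ~25 mm lever that is nearly stationary over
  the extension end — because the stop force is then fixed by moment
  balance, the ACL force is insensitive to cartilage stiffness (CV
  ≈ 0.3 %), matching the observed indifference of the ACL.  The PCL
  engages ~23° above neutral and stops flexion; its femoral attachment
  is placed so the cable is *isometric at the extension end*, where it
  acts as the check-rein of the anterior femoral glide: a taut cable
  with zero lever transmits no torque noise into the ACL balance.
* **Collaterals as preload.**  The MCL (pretensioned, near-vertical) is
  isometric near full extension and acquires an extension-restoring
  lever only in deep flexion; the LCL is short, soft and near-isometric
  throughout.  Together they press the condyles into the plateau
  (~185 N preload, ~0.4 mm standing indentation) without loading the
  rotation at neutral.
* **Posterior facet.**  The second condylar pair is centred 4.5 mm
  superior in the femur frame, so it engages only in deep flexion.  Its
  force — read from the same per-sample curve — injects
  cartilage-dependent torque straight into the flexion moment balance.
  This single feature is what makes the flexion-side outcomes (PCL and
  MCL peak forces, CV ≈ 2–3 %) sensitive to the material sample while
  leaving the extension side quiet, reproducing the characteristic
  per-ligament CV fingerprint.
* **Mass, inertia, damping** (4 kg, 0.05 kg·m², 3000 N·s/m,
  0.25 N·m·s/rad) are numerical settling choices of the stand-in, sized
  so the slowest rotational mode decays within each 3.2 s plateau while
  the contact mode remains stable at dt = 1 ms.

Because the stand-in is calibrated to anchors rather than copied from
the reference model, the flexion–extension outputs are *qualitative*
reproductions: group orderings, ratios and the ligament fingerprint are
meaningful; absolute angles and forces are not predictions for any real
joint.  The compression stage, by contrast, uses only printed geometry
and material ranges.

## 6. Statistics

CV uses the sample (n−1) standard deviation; the denominator is not
prescribed by the formulas being reproduced, and n−1 is the
conventional choice for batch estimates.  The variant tables interpret
the per-group "CV" as the CV of the 64 angular ranges (consistent with
RDiff operating on the same ranges).  Ligament CVs are computed from
each run's maximum flexion-branch force for PCL, LCL and MCL and the
maximum extension-branch force for the ACL (the ACL carries no force in
flexion).  Pooled statistics concatenate the two groups' batches; for
duplicated batches the pooled sample SD differs from the group SD by
the exact factor sqrt(2(n−1)/(2n−1)), which the tests assert.

## 7. Study sizes and runtime

The full compression stage (2 × 64 solves, 21 curve points each) runs
in a few seconds on one CPU.  One flexion–extension branch is 16 000
integration steps (~0.2 s); the full 4096-model second stage is ~25
CPU-minutes and is exercised end-to-end in scaled-down form (2 variants
× 8 samples × 2 groups, ~15 s) by the default test suite, which covers
every code path of the full study.  Study sizes are configuration, not
code: `StudyConfig(n_samples_override=..., n_variants_override=...)`.

## 8. Known limitations

* Sagittal-plane kinematics only; no menisci, patellofemoral joint,
  muscles or wrapping surfaces.
* Frictionless, quasi-static contact in the indentation stage; no
  penalty-contact artefacts are modelled (the surrogate assumes a clean
  physical response at small indentation).
* The foundation model underestimates the OA group's force dispersion
  (§2); OA-group spread statistics are therefore conservative.
* The reference knee's true ligament laws, masses and damping are
  unavailable; all flexion–extension numbers are anchored, not
  replicated (§5).
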