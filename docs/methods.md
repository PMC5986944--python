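# Methods

`cardiomech` builds desk-scale, fully synthetic analogues of
subject-specific beating-heart models: an orthotropic passive myocardium
with continuous infarct homogenization, time-varying elastance active
contraction, a reduced-order biventricular mechanical model coupled to a
closed-loop lumped circulation, multi-stage material calibration, DT-MRI
fiber-architecture analysis, and 16-segment endocardial strain
validation.  This note records the models, their assumptions, the
numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Passive material model

The passive response is the Holzapfel–Ogden orthotropic strain-energy
function

Ψ_iso = ā/(2b̄)·exp(b̄(Ī₁−3)) + Σ_{i=f,s} ā_i/(2b̄_i)·{exp(b̄_i(I₄ᵢ−1)²)−1}
        + ā_fs/(2b̄_fs)·{exp(b̄_fs·I₈fs²)−1}

with fiber/sheet pseudo-invariants I₄f, I₄s, I₈fs relative to a local
orthonormal frame, plus a volumetric penalty Ψ_vol = (1/D)((J²−1)/2 −
ln J).  Infarcted tissue is handled by homogenizing every linear (a-type)
coefficient with a tissue-health scalar h ∈ [0,1]:

ā_i = a_i · A · [h + (1−h)·p],

so h = 1 recovers healthy tissue and h = 0 is p = 4.56 times stiffer (the
literature-derived infarct-to-remote stiffness ratio used as the package
default).  A and B are uniform subject multipliers of the a-type and
b-type coefficients fixed in the second calibration stage.

Design choices where the published form is ambiguous:

* **Invariant split.** The isochoric split J^(−2/3) is applied to I₁
  only; I₄/I₈ are unsplit (avoids spurious fiber response under
  volumetric deformation).  A `split_i1` switch restores the unsplit
  form.
* **Tension-only anisotropy.** The I₄ terms contribute only for I₄ > 1
  (fibers carry no compressive load), configurable via `tension_only`.
* **Units of D.** D carries MPa⁻¹ (default 0.2, bulk modulus 2/D =
  10 MPa ≈ 1000× the largest linear coefficient); values outside
  (0.02, 20) trigger a warning.
* **Overflow guard.** Exponent arguments above 700 raise an error naming
  the offending term, so pathological parameter sets surface instead of
  silently producing `inf`.

The default parameter set (`HUMAN_SHEAR_PARAMS`: a = 1.05 kPa, b = 7.542,
a_f = 3.465 kPa, b_f = 14.472, a_s = 0.481 kPa, b_s = 12.548,
a_fs = 0.283 kPa, b_fs = 3.088) is the human triaxial-shear calibration
that the shear-stage self-consistency experiments treat as ground truth.

Simple shear "mode ij" means: faces with normal e_i are displaced along
e_j, and the work-conjugate Cauchy component σ_ij is reported.  This
convention is stated prominently because shear-data publications differ.

## Active contraction

Tension follows a time-varying elastance law

T_a(t, l) = T_max · Ca₀²/(Ca₀² + ECa₅₀(l)²) · (1 − cos ω(t, l))/2 · h,

acting along the deformed fiber direction, with a fraction n_s ∈ [0,1]
transferred to the sheet direction.  Multiplying by h makes contractility
proportional to tissue health; fully infarcted tissue develops no force.
Internals (all overridable on `ActiveParams`):

* length-dependent calcium sensitivity ECa₅₀ = Ca₀max/√(exp(B(l−l₀))−1)
  with Ca₀ = Ca₀max = 4.35 µM, B = 4.75 µm⁻¹, l₀ = 1.58 µm — standard
  literature constants of the underlying elastance model;
* sarcomere length from fiber stretch, l = l_R·√I₄f with l_R = 1.85 µm;
* timing ω: linear rise to π over t₀ = 160 ms, return to 2π over the
  length-dependent relaxation time t_r = m·l + b.  The classic (m, b)
  values produce a twitch longer than the 480 ms active phase of the
  cardiac cycle simulated here, so the defaults use half those slopes
  (m = 524.45 ms/µm, b = −714.5 ms), which closes the twitch within the
  phase at physiological sarcomere lengths.  This is a package choice,
  not a measured constant;
* sarcomere lengths at or below l₀ return zero tension with a warning
  rather than raising, so transient compressive states do not abort a
  simulation.

## Reduced-order ventricle

The full-heart finite-element model this package emulates is replaced by
a thick-walled truncated prolate ellipsoid with two kinematic degrees of
freedom: cavity volume V and long-axis stretch λL.  The wall deforms by
the axisymmetric, torsion-free map

z = λL·Z,    r² = R²/λL + φ₀·g(Z),    g(Z) = ((1 − Z²/c_endo²)₊)²,

whose Jacobian is **identically one** for any meridional profile g — the
wall is exactly incompressible and every transmural shell conserves its
enclosed volume, so no volumetric penalty is needed in the internal
energy (its exclusion also makes the passive P(V) curve exactly
homogeneous of degree one in the a-type coefficients).  The amplitude φ₀
follows from the prescribed cavity volume in closed form.  The squared
profile vanishes C¹-smoothly at the endocardial apex, keeping the solid
apex column on the axis without shear concentration.

Cavity pressure and the long-axis balance come from virtual work over a
Gauss quadrature of the wall (default 5 transmural × 8 longitudinal
points, axisymmetric; 16 circumferential stations when an infarct breaks
axisymmetry):

P = ∂W_int/∂V  at the λL solving ∂W_int/∂λL = 0,

with the λL root found by a quasi-Newton iteration warm-started across
calls.  Because the admissible variations are isochoric, the hydrostatic
part of the stress is indeterminate and irrelevant to both balances.

Fidelity and limitations of the two-DOF family:

* The thin-wall spherical limit reproduces the Laplace-law pressure
  P = 2σt/r within ~1% (checked against the closed-form membrane
  solution).
* The classic incompressible thick-sphere solution r³ = R³ + a³ − A³ is
  matched only approximately (equatorial-band stretches within ~3–4% at
  10% volume inflation); the family cannot represent the closed-sphere
  displacement field near the poles.  Pointwise stress fields should be
  read as qualitative; cavity-level quantities (P, V, λL) are the
  model's reliable outputs.
* Torsion is not a kinematic DOF; torsional motion enters only through
  the analytic motion generator used for strain-mapping validation.
* The default LV geometry (a_endo = 12.4, c_endo = 40, a_epi = 22,
  c_epi = 48, z_base = 10 mm) gives an unloaded cavity of ≈17.6 ml and a
  ≈46 cm³ wall — porcine left-ventricle scale.  The RV reuses the same
  machinery with a thinner wall (14/42/19/47 mm) and the same material
  parameters.

mmHg↔kPa conversion is fixed at 1 mmHg = 0.133322 kPa and centralized in
`cardiomech.units`.

## Closed-loop circulation

Three linear compliance compartments — systemic arteries (SA), systemic
veins (SV), pulmonary circuit (P) — connect to the two ventricles through
five unidirectional Ohmic resistances (P→LV mitral, LV→SA aortic,
SA→SV systemic, SV→RV tricuspid, RV→P pulmonary).  Compartment pressures
are P = (V − V(0))/κ; flows are Q = max(ΔP, 0)/R.  Ventricular inflows
are additionally gated shut during the entire 480 ms active phase;
outflows are purely pressure-gated at all times.  Each cycle is 480 ms
active contraction + 300 ms passive filling (780 ms, 77 bpm).

Integration is explicit Euler with a 1 ms default step; volume updates
are pairwise transfers, so total circulatory volume is conserved to
round-off by construction.  No valve-event location is needed: the gated
Ohmic flow is continuous in the state, and phase boundaries fall on exact
step multiples.  Halving the step changes the converged stroke volume by
under 0.5% (tested), which is why the 2 ms step used inside calibration
loops is adequate.

Default constants (the reference publication's own values are not
reprinted there; these are package choices tuned once for physiological
porcine hemodynamics at the study scale — MAP ≈ 90 mmHg, pulse pressure
≈ 40 mmHg at a ~31 ml stroke volume, central venous ≈ 5 mmHg):
κ_SA = 0.8, κ_SV = 25, κ_P = 8 ml/mmHg; R_M = 40, R_A = 60,
R_SYS = 2000, R_T = 40, R_P = 50 mmHg·ms/ml.  Initial conditions load
each compartment to its end-diastolic pressure by inverting the
compliance relation (defaults 80/6/12 mmHg for SA/SV/P) and start the
ventricles at their end-diastolic volumes.

## Calibration

Three stages, mirroring the subject-specific calibration workflow:

1. **φ₁ — shear.**  Bounded trust-region-reflective least squares of the
   eight passive parameters against six-mode simple-shear data,
   objective Σ_modes Σ_j (σ − σ̄)².  Noiseless self-consistency
   experiments recover the printed parameter set to machine precision
   from ±30% perturbed starts.  Under 1% multiplicative noise the
   isotropic and fiber parameters recover within 5%, but the sheet and
   fiber-sheet exponents are weakly identified (the objective is nearly
   flat along correlated (a_i, b_i) directions of the low-stress modes);
   the curves themselves are always recovered to R² > 0.999.
2. **φ₂ — Klotz scaling.**  The uniform multipliers (A, B) are fitted so
   the ventricle's passive inflation curve matches a single-beat
   end-diastolic PV relation through the subject's (EDV, EDP) anchor:
   objective Σ_j (P_j − P̄_j)² + (EDV − ĒDV)², where the model EDV is the
   volume at which the curve reaches the target EDP.  The EDPVR uses the
   normalized-volume form P = An·V̄^Bn (An = 28.2 mmHg, Bn = 2.79,
   overridable) with V30 from the single-beat estimate and the model's
   known unloaded volume V₀ — the curve passes exactly through the
   anchor and is zero at V₀.  RV pressurization is represented by an
   optional trans-septal pressure offset on the LV curve (the reduced
   geometry has no shared septum); it defaults to zero.
3. **φ₃ — active.**  (T_max, n_s) fitted on the **first simulated beat**
   of the coupled model, objective (SV − S̄V)² + 0.2·(LVLS − L̄VLS)², the
   long-axis-shortening term acting as a low-weighted regularizer that
   rejects elongating solutions.  Because stroke volume rises steeply
   once peak ventricular pressure crosses the arterial afterload, a pure
   gradient start can stall on the zero-SV plateau; the fit therefore
   first brackets T_max on the SV target (log-spaced scan + bisection,
   with forward-model failures at high tension treated as overshoot) and
   then polishes both parameters by bounded least squares, repeating the
   bracket+polish pair once so a ridge-stalled polish restarts from the
   updated n_s.  (T_max, n_s) are partially degenerate along an
   iso-(SV, LVLS) ridge; recovery experiments therefore perturb around
   the true values rather than starting arbitrarily far away.

Hemodynamic target sets ship for a normal profile (EDV 57.8 ml, SV
30.9 ml, EF 53.4%, RV EDP 4 mmHg) and a heart-failure profile (EDV
103.0 ml, SV 33.0 ml, EF 32.0%, RV EDP 8 mmHg).  The LV EDP values
(10/20 mmHg) are documented assumptions consistent with the heart-failure
subject's roughly doubled filling pressure; LVLS targets default to 15%
with the 0.2 weight.

## Fiber-architecture analysis

Diffusion tensors are eigen-decomposed (primary eigenvector = myofiber);
quality control keeps voxels with strictly positive eigenvalues and
fractional anisotropy above 0.12.  Interpolation to arbitrary points is
invariant-based: eigenvalues trilinearly, orientations by sign-aligned
weighted quaternion averaging (signs aligned to the largest-weight
neighbour), reassembled as R·diag(λ)·Rᵀ — an approximation of invariant
tensor-interpolation schemes; the exact invariant set of the published
method is not reproduced.  The inclination (helix) angle α_h is the
fiber's angle to the circumferential direction after projection into the
circumferential–longitudinal tangent plane, folded into (−90°, 90°];
near-radial fibers are flagged undefined and excluded from statistics.

Regional statistics use the AHA 17-segment map: basal/mid/apical thirds
with 6/6/4 sectors, the sector origin at the anterior RV insertion, and
an apical cap defined as the apex-most sixth of the long axis (the
guidelines give no depth rule; configurable).  The transmural coordinate
is the shell coordinate of the ellipsoidal wall normalized to −1
(endocardium) … +1 (epicardium).

The continuous tissue-health field is built from a binary segmentation
(1 healthy / 0 infarct) by trilinear interpolation — values strictly
between 0 and 1 appear only in the border zone, and enlarging the
infarct mask can never increase h anywhere.

## Strain mapping

The endocardial surface is partitioned into the 16-segment echo model
(12 quadrilateral trunk segments + 4 apical triangles converging at the
apex).  Control nodes at segment corners and edge midpoints are
identified with surface vertices at end-diastole and tracked by index
through all frames.  Natural cubic splines (chord-length parameterized)
through the circumferential and longitudinal control rows give segment
curves; engineering strain is the percent arc-length change relative to
end-diastole (zero at ED by construction, invariant under rigid-body
motion).  Global strains (GLS/GCS) are area-weighted means of segment
strains (ED triangle areas; an unweighted option exists).  Arc lengths
use fixed-order Gaussian quadrature per spline interval; doubling the
order changes strains by < 0.01%.

## Synthetic data

Every input class is generated with a seeded `numpy` Generator and
emits ground truth alongside the data:

* **DT phantom**: 1 mm isotropic voxels of the ellipsoidal wall, tensors
  with eigenvalues (1.0, 0.7, 0.5)×10⁻³ mm²/s whose primary eigenvector
  follows a linear transmural helix-angle rule (+60° endo → −60° epi),
  orientation noise as rotations about random axes with N(0, 5°) angles,
  10% of wall voxels and the whole background isotropic (FA below the
  0.12 gate by construction).
* **Infarct**: an ellipsoidal blob inside the wall as a binary mask; the
  ground-truth h uses the same trilinear rule as the h-field builder.
* **Shear curves**: the forward model itself over γ ∈ [0, 0.5] (the
  range of the triaxial experiments) with multiplicative N(1, σ) noise.
* **Motion**: an analytic beating ellipsoid (uniform circumferential
  shortening, long-axis shortening about the base plane, torsion linear
  in distance from the base) sampled at 11 frames with a sin² amplitude
  ramp; per-segment circumferential strain is exact in closed form and
  longitudinal ground truth integrates the deformed meridian densely.
  Vertices sit at sector half-steps so none falls on a segment boundary.

What passing these tests shows: the pipeline stages are internally
consistent and recover known ground truth under the stated noise models.
What they do not show: robustness to real-data features absent from the
generators — acquisition noise floors and eddy currents in DT-MRI,
segmentation errors, papillary muscles and trabeculation, non-ellipsoidal
geometry, breath-hold and probe-angle variability in echo strain.

## Problem sizes

Default experiment sizes are chosen for single-workstation runs: 40
wall quadrature points per ventricle (axisymmetric), 1 ms circulation
steps (2 ms inside calibration loops), six simulated cycles for the
limit-cycle study, ~10⁵-voxel DT phantoms, and 20-point six-mode shear
curves.  The acceptance script (`scripts/acceptance.py`) re-runs the
shear recovery, the beat-one active calibration plus six-cycle
convergence study, and the volume-conservation check at exactly these
sizes.

## Known limitations

* Two kinematic DOFs cannot represent regional wall-motion
  abnormalities; infarcts affect global function only through stiffness
  and lost contractility.
* The long-axis balance is an energy argument on a constrained family;
  long-axis shortening magnitudes are indicative (the calibration
  treats LVLS as a low-weighted target for exactly this reason).
* No atria, pericardium, inertance, baroreflex, viscoelasticity or
  electrophysiology.
* The φ₁ noise experiments show the sheet/fiber-sheet exponents are
  weakly identified from six-mode shear data alone — a property of the
  experiment design, not of the optimizer.
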