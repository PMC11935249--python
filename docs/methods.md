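# Methods

This note documents the models behind `letimpt`, the defaults and why they
were chosen, what the synthetic phantom does and does not emulate, and the
numerical conventions a user should know before trusting or changing the
results.

## Phantom and planning geometry

The phantom is a voxelized pelvis surrogate: an elliptic water cylinder
(semi-axes 75 x 65 mm, density 1.0 g/cc; 0.001 g/cc outside), an
ellipsoidal CTV (semi-axes 20 x 18 x 18 mm) at the isocenter, a bladder
ellipsoid abutting anteriorly, a rectum cylinder (radius 12 mm, along the
superior-inferior axis) abutting posteriorly, and two bone-like ellipsoids
(density 1.5 g/cc, semi-axes 15 x 25 x 45 mm) centered laterally at
x = +/-55 mm so that lateral beams traverse heterogeneity. The bone
z-semi-axis (45 mm) spans the target's full superior-inferior extent, as
femoral bone does at prostate level; this keeps the bone-thickness
gradients where lateral beams actually stop rather than at the CTV's
superior/inferior fringe. The default grid is 64 x 64 x 48 voxels at
2.5 mm, chosen for minutes-scale runtimes; everything is configurable.

Conventions: +x patient left, +y posterior, +z superior; voxel centers
carry the world coordinates; a voxel is in an ROI iff its center satisfies
the shape predicate. Gantry angles are IEC-style coplanar (0 deg enters
anteriorly, 90 deg from patient left), which makes the 270/90 pair the
standard lateral-opposed prostate arrangement. The scanning target volume
(STV) is the anisotropic CTV expansion with margins 12 mm lateral, 6 mm
anterior, 4 mm posterior, 5 mm superior/inferior, implemented as a
union-of-asymmetric-ellipsoids (octant-wise margins) via morphological
dilation — the common TPS convention. The prescription is 78 Gy(RBE) in
39 fractions at constant RBE 1.1; all doses are dose-to-water times 1.1.

## Shared beam physics

Both engines close over the same two-parameter Bragg-Kleeman model,
R = alpha E^p with alpha = 2.2e-3 cm/MeV^p and p = 1.77, which matches
CSDA water ranges to a few percent over 70-230 MeV — adequate at desk
scale, and replaceable by measured tables. Range straggling is Gaussian
with sigma_R = 1.2% of R (typical water value). Multiple Coulomb
scattering uses the Highland formula in the small-angle Gaussian
approximation with the water radiation length scaled by local density;
the logarithmic thickness correction is dropped so the same scattering
power can be accumulated per step (stochastic engine) and integrated in
closed form (Fermi-Eyges, analytical engine) — the two lateral models are
then consistent by construction, which is what makes broad-field
agreement a property rather than a coincidence. LET means the
unrestricted electronic stopping power of the primary proton in water
(keV/um), tabulated against residual range and clamped below 0.1 mm
residual; secondary-particle LET is out of scope.

## The two dose engines and their deliberate asymmetries

**Analytical pencil-beam (PB).** Each spot's integrated depth-dose (IDD)
is the Bragg-Kleeman stopping profile averaged over the Gaussian range
distribution (computed by quadrature after the substitution r = t^2,
which removes the end-of-range singularity; the IDD area equals the
initial energy). A spot's dose column is IDD(water-equivalent depth along
the *central ray only*) times a single lateral Gaussian with
sigma^2(z) = sigma_initial^2 + sigma_MCS^2(z). Dose is scored as the
voxel mean: the IDD is averaged over the voxel's WEPL interval and the
lateral Gaussian integrated over the voxel cross-section (erf), so both
engines estimate the same physical quantity (mean dose to the voxel) and
their residual differences are modeling differences, not discretization
artifacts.

**Stochastic engine (MC).** Histories sample an individual range from
N(R, sigma_R) and an initial lateral position (sigma_initial = 4 mm),
then step through the density grid (step = half the smallest voxel
dimension) depositing midpoint-rule energy losses, with Highland angular
kicks whose variance is accumulated over four substeps per applied kick
(diffusion-equivalent at these step lengths, several times cheaper in
random numbers). Each deposit is indexed by its segment midpoint so
deposits never sit on voxel boundaries. Dose x LET is scored with the
transported proton's own residual-range LET; voxel LET_d is the ratio of
the accumulated sums. Per-spot streams are keyed by (seed, spot id), so
influence assembly is order-independent and bitwise reproducible.

The engines agree in homogeneous water: laterally integrated depth-dose
to <0.1%, single-spot lateral sigma to ~2%, broad-field central-axis dose
within 2% of the peak proximal to the distal 80% fall-off. Their
*deliberate* differences, mirroring the weaknesses of the analytical
algorithm class, are: (a) the PB engine sees heterogeneity only through
the central-axis radiological depth, while stochastic protons at lateral
offsets stop where their own paths dictate — the dominant effect near
bone-thickness gradients; (b) only the stochastic engine has a nuclear
low-dose halo surrogate: a fraction (default 0.005) of histories is
rerouted to a 5x wider initial Gaussian. The halo fraction is a
calibration, not a measured value: it must be small enough that flat
broad-field plans recalculate consistently across engines (the halo's
uniform core loss is otherwise compensated by the LET-stage optimizer and
washes out the patch signal), yet nonzero so the narrow-field envelope
inequality is strict. 0.005 satisfies both on the default phantom;
(c) stochastic noise, reported as a batch-based relative standard error.

## Spot placement and scenarios

Per beam, energy layers span the STV's WEPL interval along that beam with
a spacing equal to the deepest pristine peak's width at 80% of its
maximum (floored at 2 mm); lateral spots sit on a square grid at
1.5 sigma_initial, kept only where an STV voxel lies within one spacing
box in (u, v, WEPL) space. The coverage contract — every STV voxel within
one lateral spacing and one layer spacing of some spot's peak — is
audited by brute force in the tests. The robust scenario set is the
standard nominal + 8: +/-5 mm rigid setup shifts along each axis and
+/-3.5% density scaling (range uncertainty), magnitudes typical for
prostate and configurable; combined setup+range scenarios are not
included. Setup shifts move the beam isocenter; range scaling multiplies
the density map.

## Optimization

The composite cost is a weighted sum of per-structure mean-squared
penalties. Dose kinds: uniform (d - ref), one-sided max/min hinges, a
hinged mean, and a hinged gEUD. Robust-flagged objectives (the targets)
are evaluated each iteration on their worst scenario (ties broken by
lowest scenario index); OAR objectives use the nominal scenario —
*selective* robustness. The simplified planning directive used by
default: STV uniform at 1.02 x prescription (robust), CTV uniform at
1.02 x prescription (robust), CTV minimum dose at 1.015 x prescription,
max-dose caps at the prescription on rectum and bladder, and a mild body
hotspot cap at 1.07 x prescription. The 2% target overshoot mirrors
routine prostate normalization and puts nominal D98 just above the
prescription.

The LET stage keeps the dose objectives (evaluated on the stochastic
influence, nominal scenario — the scenario set applies to the dose-only
stage) and adds hinge-quadratic LET terms with the exact ratio gradient
dL_i/dw_j = (c_ij - L_i d_ij) / sum_k w_k d_ik; zero-dose voxels are
excluded. Defaults: CTV goal 4.5 keV/um with weight 40, OAR caps
3 keV/um with weight 2. The goal and weights are the knobs that set how
hard the optimizer trades longitudinal dose uniformity for distal-edge
patching; the defaults were fixed once, during design, at the values that
produce a clear ramp-and-patch geometry while the post-hoc gEUD criteria
(CTV within 2%; rectum/bladder increase bounded by 2% or 2 Gy(RBE), with
exponents a = -10, 11.11, 2) remain satisfied.

Weights are optimized by projected quasi-Newton descent (L-BFGS-B) under
w >= 0, warm-starting the LET stage from the dose-stage weights
(sequential workflow). Initialization: uniform weights scaled so the mean
STV dose equals the prescription. Defaults: 300 iterations cap,
ftol 1e-11; the best evaluated iterate is returned, so the objective
never exceeds its starting value. Hinge kinks use one-sided derivatives;
the worst-scenario selection makes the objective piecewise smooth, which
L-BFGS-B handles well in practice at these sizes (~2,300 spots, ~7,000
robust voxels).

## Evaluation

DVH indices are exact sorted-voxel quantiles (no binning): Dv is the
ceil(v n)-th largest dose; D1cc interpolates the cumulative absolute
volume at exactly 1 cc; binned DVH export (0.1 Gy) exists for plotting
only. gEUD is (mean d^a)^(1/a), computed with the extremum factored out
so large |a| cannot overflow, and with zero doses floored at 0.01 Gy for
negative a. LET_d maps flag zero-dose voxels; CTV LET indices exclude
them and refuse to evaluate if they exceed 5% of the CTV. Cross-engine
deltas follow the two printed conventions: (MC - PB)/PB x 100 for
dose-optimized plans and (PB - MC)/MC x 100 for LET-optimized plans. The
exact Wilcoxon signed-rank test enumerates all 2^n sign assignments
(subset-sum doubling), uses mid-ranks for ties, drops zero differences,
and doubles the smaller tail capped at 1 — one documented convention
among several.

## Workflow, sizes and runtimes

The four-step pipeline per arrangement: (1) PB influence over all nine
scenarios (perturbed-scenario columns stored only on the robust target
voxels — the only rows worst-case evaluation reads) and dose-only robust
optimization; (2) stochastic recalculation of those weights (default
2e4 histories/spot; ~0.3% CTV standard error) giving the MC dose and the
first LET_d map; (3) stochastic influence at 2e3 histories/spot (the
cheaper optimization-grade dose of clinical practice) and LET
re-optimization, then a 2e4-history recalculation for the final MC dose
and second LET_d map; (4) PB recalculation of the LET-optimized weights.
Per-beam mid-STV profiles are rendered from the PB influence. On the
default phantom the two-field pipeline is ~2,300 spots and runs in about
8 minutes on one CPU; these sizes are the package's working scale, set so
the full comparison remains an interactive desk experiment.

Per-plan and per-stage random streams are derived from the master seed,
so reruns are bitwise identical and plans are independent. Failure
isolation is per arrangement.

## What the phantom does and does not show

The phantom reproduces the *mechanism*: flat target-stopping fields under
dose-only robust optimization, ramp-like distally patched fields under
LET optimization, cross-engine agreement for the former and distal-edge
sensitivity for the latter, concentrated where beams stop on
heterogeneity gradients. It is one synthetic geometry: absolute delta
magnitudes depend on its bone shapes and on the halo calibration, its
heterogeneity is far milder than a real pelvis CT, there is no
inter-patient anatomy distribution (the cohort module jitters sizes and
positions around one template and is labeled synthetic), no secondary
particles, no deliverability constraints, and no variable-RBE model.
Passing tests demonstrate the workflow and the direction and ordering of
the effects, not patient-cohort dose statistics.

## Known limitations

- The Bragg-Kleeman closure underestimates the sharpness of real measured
  IDDs at low energy; both engines share the bias, so comparisons are
  unaffected, but absolute depth-dose shapes are approximate.
- The stochastic engine transports primaries only; the halo surrogate
  redistributes fluence laterally without the energy/range degradation of
  true nuclear products.
- The LET-stage optimization is nominal-scenario only; robustness of
  LET-optimized plans to setup/range error is itself poor (visible by
  rendering perturbed scenarios) and is not optimized for.
- Exact Wilcoxon enumeration is capped at n = 20 pairs.
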