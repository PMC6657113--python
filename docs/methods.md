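# Methods

## Physical model

Blood is treated as an incompressible Newtonian fluid of density
ρ = 1.025 g/mL and dynamic viscosity μ = 4.0·10⁻³ Pa·s. Both are exposed in
`EnergeticsParams`; ρ is the standard value for whole blood, and μ is the
conventional Newtonian approximation for large-vessel/intracardiac flow at
physiological hematocrit. Per cardiac phase `t`, over the in-mask voxels of
volume dV:

- **Kinetic energy** KE(t) = Σ ½ ρ dV |v|², the voxel mass being ρ·dV.
- **Viscous energy-loss rate** EL(t) = μ Σ dV φ_v with the dissipation
  function φ_v = ½ Σ_ij [(∂v_i/∂x_j + ∂v_j/∂x_i) − ⅔(∇·v)δ_ij]².
  For a solenoidal field this is the classical incompressible dissipation
  2 e_ij e_ij; the −⅔(∇·v) term is retained because measured
  phase-contrast fields are never exactly divergence-free. For every
  analytic phantom the divergence vanishes, so the oracles are unaffected.
- **Volumetric vorticity** vorticity_vol(t) = Σ |∇×v| dV. The magnitude is
  taken per voxel *before* integration, so the quantity is direction-blind
  and counter-rotating vortices add instead of cancelling.

Internally everything is SI (velocity m/s, length m); spacing is stored in
mm and results are scaled to mJ, mW and mL/s only at the reporting
boundary. Phase averages over systole, diastole and the cycle weight all
phases equally: retrospective gating reconstructs uniformly spaced phases,
and no per-phase duration information exists in the inputs. Whether a
duration-weighted average would be preferable is moot under that sampling.

## Spatial derivatives at the chamber boundary

Velocities outside the segmentation are undefined (air, myocardium,
noise), so gradient stencils never cross the mask boundary: central
differences are used where both axis neighbours are in-mask, one-sided
differences where only one is, and the derivative is set to zero along an
axis with no in-mask neighbour. Grid edges count as out-of-mask. Central
*and* one-sided stencils are exact on linear fields, which is what makes
the solid-body-rotation phantom an exact oracle (|∇×v| = 2Ω and zero
strain everywhere, including the boundary shell).

## Aliasing correction

Phase-contrast MRI records velocity modulo the encoding limit: the forward
model folds v into [−venc, venc) via ((v + venc) mod 2 venc) − venc. The
corrector assumes at most a single wrap (true |v| < 2 venc) and spatial
smoothness of the true field. A per-voxel rule that compares each voxel to
the median of its in-mask 6-neighbourhood in a single pass cannot repair a
contiguous wrapped region — interior wrapped voxels agree with their
wrapped neighbours — so the rule is applied by deterministic region
growing: each connected mask component is traversed breadth-first from a
reproducible seed (the voxel with the most in-mask neighbours, ties broken
by lowest index); a voxel differing from the median of its already-resolved
neighbours by more than venc receives the single ±2·venc correction that
minimises the difference. Because the seed itself may sit in a wrapped
region, a final per-component branch fix shifts the whole component by the
member of {−2 venc, 0, +2 venc} that leaves the most voxels at their
recorded values. On a noise-free smooth field whose adjacent-voxel velocity
differences stay below venc, the reconstruction is exact; with noise,
voxels within O(noise) of the decision threshold can mis-resolve, which is
the same failure mode interactive unwrapping tools have.

## Rigid mask alignment

The registration that aligns the cine-derived segmentation to the 4D-flow
acquisition is estimated elsewhere; only the application of a given rigid
transform is implemented. The mask is resampled with nearest-neighbour
interpolation on the same grid (binary in/out, no partial-volume
weighting), with out-of-grid voxels set to background. Nearest-neighbour
round trips (T then T⁻¹) perturb only a boundary shell; the affected
fraction scales with the surface-to-volume ratio of the chamber and stays
at the few-percent level for chamber-sized masks at ~1 mm resolution.

## Volumetrics

Chamber volume is voxel counting times dV. ED and ES are defined as the
phases attaining the maximal and minimal volume — a deterministic
convention; ECG-based frame selection would need information the mask
series does not carry. SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR.
Sphericity is the ratio of axis-aligned bounding-box extents
(width axis / long axis, both configurable, measured at the ED and ES
phases). Note this is a 3D bounding-box surrogate for what is classically
measured on 2D cine slices; on ellipsoidal phantoms the two coincide.

## Phantoms and what they do (not) emulate

Each phantom samples an exact analytic field at voxel centres and carries
its closed form: uniform flow (KE = ½ρV|v|², EL = vorticity_vol = 0),
solid-body rotation (vorticity_vol = 2ΩV, EL = 0, exact on the lattice),
Poiseuille pipe (EL = 2πμLv_max², KE = ρv_max²V/6) and a Lamb–Oseen vortex
(vorticity_vol = Γ·L for domain radius ≥ 4 r_c). Pulsatility multiplies a
base field by per-phase scalars, preserving analytic per-phase oracles;
noise is additive i.i.d. Gaussian per component (no Rician magnitude bias,
no eddy-current offsets, no k-space physics). Masks are generated by an
in/out test at voxel centres without anti-aliasing.

For the Poiseuille discretization study the grid is chosen so the cylinder
wall falls exactly on the outermost voxel-center ring
(spacing = 2R/(n−1)). With that alignment the leading error is the
systematic O(h) one-sided stencil error at the wall, which decreases
monotonically under refinement; with an arbitrary wall/lattice alignment
the error is dominated by sub-voxel boundary assignment and fluctuates
non-monotonically at the 0.1–0.3 % level. Verification problem sizes are
32³–128³ single-phase grids, which resolve the reference pipe at 0.3–1.3 mm
— comparable to clinical 4D-flow voxel sizes.

## Cohort simulator

The generator emulates the *group-level* statistics of a ten-patient
single-ventricle stress cohort: VO₂max ~ N(30.2, 8.6²) mL/kg/min; rest
cycle-averaged KE, EL and vorticity_vol ~ positive-truncated normals with
means ± SD of 1.8 ± 0.5 mJ, 0.9 ± 0.4 mW and 3441 ± 899 mL/s; relative
rest-to-stress differences Δ% = a + b·VO₂max + ε chosen so that the
population means ± SD are 88 ± 52 %, 108 ± 49 % and 27 ± 19 % with planted
correlations of −0.83, −0.80 and −0.64 respectively. Stress values are
rest·(1 + Δ/100), so the planted Δ is recoverable from the table exactly.
The simulator does not model measurement error on the imaging metrics,
inter-metric correlation beyond the shared VO₂max term, or heart-rate
dependence — passing tests demonstrate the pipeline's statistical
behaviour under the planted model, not the physiology of any real cohort.
At n = 10 the sampling error of a correlation coefficient is large
(Fisher-z SE ≈ 0.38), so single-cohort correlation values scatter widely
around the planted ones; recovery is asserted at n = 200.

## Statistical pipeline

Shapiro–Wilk at α = 0.05 gates every branch. Paired comparisons test the
difference vector d = stress − rest (the gate is applied to d, not to each
arm): paired t when d passes, Wilcoxon signed-rank otherwise (exact null
distribution for n ≤ 25 without ties, normal approximation with continuity
correction above). Correlations use Pearson only when *both* variables
pass the gate, Spearman otherwise — the conservative reading of
"non-parametric in case of non-normality". Descriptives follow the same
gate: mean ± sample SD (n−1) versus median [IQR]. Correlation strength is
classified on |r| with boundary ties assigned to the weaker band
(poor < 0.5 ≤ moderate ≤ 0.70 < good ≤ 0.85 < strong ≤ 0.95 < excellent);
the interval endpoints are ambiguous in common usage, so the tie-break is
fixed and tested. Degenerate cases are explicit decisions: an all-zero
difference vector returns p = 1 with a warning; a (near-)constant sample
is reported non-normal with p = 0; zero-variance correlation inputs raise.
All tests are two-sided at α = 0.05 with no multiple-testing correction,
matching standard practice for exploratory cohort studies of this size.

## Known limitations

- Turbulent kinetic energy, pressure drops and wall shear stress are out
  of scope.
- The EL estimate inherits the usual finite-difference bias near the
  boundary shell; it converges to the continuum value only as resolution
  increases relative to the shear-layer thickness.
- The unwrapping corrector handles single wraps only and assumes spatial
  smoothness; double-wrapped or pathologically noisy data need the
  acquisition-side fix (higher VENC).
- Sphericity from 3D bounding boxes differs from slice-based calliper
  measurements on non-ellipsoidal chambers.
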