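# ventriflow

Intraventricular hemodynamics from 4D-flow cardiovascular MR: voxel-wise
**kinetic energy (KE)**, **viscous energy-loss rate (EL)** and **volumetric
vorticity (vorticity_vol)** over a time-resolved chamber segmentation, with
cardiac-phase averaging, ventricular volumetrics (EDV/ESV/SV/EF/CO,
sphericity), and the normality-gated paired rest-vs-stress statistical
pipeline used in small-cohort stress-imaging studies (e.g. dobutamine stress
in Fontan patients, where blunted exercise capacity is linked to inefficient
intraventricular flow).

## What it computes

Given a three-component velocity field v(x, t) in m/s on a regular voxel
grid (spacing in mm, `nt` cardiac phases) and a per-phase binary chamber
mask, per phase:

- **KE** = Σ_voxels ½ ρ dV |v|² — reported in mJ, with blood density
  ρ = 1.025 g/mL;
- **EL** = μ Σ_voxels dV φ_v — reported in mW, with the Newtonian
  dissipation function
  φ_v = ½ Σ_ij [(∂v_i/∂x_j + ∂v_j/∂x_i) − ⅔(∇·v)δ_ij]²
  and dynamic viscosity μ = 4.0·10⁻³ Pa·s by default;
- **vorticity_vol** = Σ_voxels |∇×v| dV — reported in mL/s (magnitude
  before integration, so counter-rotating structures add rather than
  cancel).

Each series is averaged over systole, diastole and the complete cycle, and
normalised by stroke volume. Spatial derivatives use mask-aware stencils
(central where possible, one-sided at the chamber boundary) so that no
stencil ever reads velocities outside the segmentation.

The package also provides: NIfTI I/O for velocity triplets and masks,
a VENC aliasing forward model and deterministic unwrapping, application of
a given rigid transform to a mask series, analytic flow phantoms with
closed-form oracles (uniform flow, solid-body rotation, Poiseuille pipe,
Lamb–Oseen vortex, beating ellipsoid), and a seeded cohort simulator with a
planted VO₂max association.

## Worked example

```python
import numpy as np
import ventriflow as vf
from ventriflow import phantom

# Poiseuille pipe: R = 10 mm, L = 50 mm, v_max = 1 m/s on a 64^3 grid
n = 64
grid = vf.VoxelGrid(n, n, n, 20/(n-1), 20/(n-1), 51.2/(n-1), nt=1)
field, mask = phantom.make_poiseuille(grid, 10.0, 50.0, 1.0)

print("KE  (mJ):", vf.kinetic_energy(field, mask)[0])
print("EL  (mW):", vf.energy_loss_rate(field, mask)[0])
print("exact EL:", 2*np.pi*4e-3*0.05*1e3)
```

prints

```
KE  (mJ): 2.7042326964509567
EL  (mW): 1.2442350495592334
exact EL: 1.2566370614359172
```

i.e. the computed viscous loss is within 1% of the closed form
EL = 2πμLv_max² for laminar pipe flow, and the kinetic energy within 1% of
ρ v_max² V / 6. On a cohort table the study stage runs the full statistics:

```python
df = phantom.simulate_cohort(phantom.CohortSpec(n_subjects=10, seed=1))
report = vf.analyze_cohort(df)
print(report.correlation_table())
```

```
  parameter         r   P-value    method strength   n
0        ke -0.915152  0.000204  spearman   strong  10
1        el -0.793939  0.006100  spearman     good  10
2      vort -0.357576  0.310376  spearman     poor  10
```

showing, for this draw, the planted inverse association between VO₂max and
the relative rest-stress increase of each energetic metric.

A CLI mirrors the library: `ventriflow phantom`, `ventriflow cohort`,
`ventriflow subject --config subject.yaml --condition rest`, and
`ventriflow study --manifest manifest.yaml --out report/`.

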