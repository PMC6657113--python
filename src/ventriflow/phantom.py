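"""Analytic flow phantoms and synthetic cohorts with closed-form oracles.

Each velocity phantom is an exact analytic field sampled at voxel
centres, shipped with the closed-form value of the quantity it is meant
to exercise:

* uniform flow        KE = 1/2 rho V |v|^2,  EL = 0,  vorticity_vol = 0
* rigid rotation      |curl| = 2*Omega everywhere, vorticity_vol = 2*Omega*V,
                      EL = 0 (linear field, zero strain rate)
* Poiseuille pipe     EL = 2 pi mu L v_max^2,  KE = rho v_max^2 V / 6
* Lamb-Oseen vortex   omega_z(r) = (Gamma / pi r_c^2) exp(-r^2/r_c^2),
                      vorticity_vol = Gamma * L (domain radius >= 4 r_c)

plus a beating-ellipsoid mask series with known per-phase volumes, an
additive-Gaussian noise model, pulsatile per-phase modulation, and a
paired rest/stress cohort simulator whose relative differences carry a
planted linear association with VO2max. Every random draw flows through
an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import SegmentationMask, VelocityField, VoxelGrid

_AXES = {"x": 0, "y": 1, "z": 2}


def _axis_index(axis) -> int:
    return _AXES[axis] if isinstance(axis, str) else int(axis)


def _grid_center_mm(grid: VoxelGrid) -> tuple[float, float, float]:
    return (
        (grid.nx - 1) * grid.dx / 2.0,
        (grid.ny - 1) * grid.dy / 2.0,
        (grid.nz - 1) * grid.dz / 2.0,
    )


def _cylinder_mask(grid: VoxelGrid, radius_mm: float, length_mm: float, axis: int) -> np.ndarray:
    """In/out test at voxel centres for a centred axis-aligned cylinder."""
    x, y, z = grid.coordinates_mm(center=_grid_center_mm(grid))
    coords = [x, y, z]
    ax = coords.pop(axis)
    r2 = coords[0] ** 2 + coords[1] ** 2
    inside = (r2 <= radius_mm ** 2) & (np.abs(ax) <= length_mm / 2.0)
    return np.broadcast_to(inside, grid.shape).copy()


def _repeat_phases(vol3: np.ndarray, nt: int) -> np.ndarray:
    return np.repeat(vol3[..., None], nt, axis=3)


def make_uniform(grid: VoxelGrid, v_vec, venc: float = 1.5) -> tuple[VelocityField, SegmentationMask]:
    """Constant velocity everywhere; mask covers the full grid."""
    v = np.empty((*grid.shape, grid.nt, 3))
    v[...] = np.asarray(v_vec, dtype=float)
    mask = np.ones((*grid.shape, grid.nt), dtype=np.uint8)
    return VelocityField(grid, v, venc=venc), SegmentationMask(grid, mask)


def make_rigid_rotation(grid: VoxelGrid, omega: float, axis="z",
                        radius_mm: float | None = None, length_mm: float | None = None,
                        venc: float = 1.5) -> tuple[VelocityField, SegmentationMask]:
    """Solid-body rotation v = Omega x r about the grid centre.

    omega in 1/s. The mask is a centred cylinder about the rotation axis
    (defaults: as large as fits in the grid). The velocity is linear in
    position, so finite differences are exact: vorticity_vol = 2*Omega*V
    and the strain rate — hence EL — is identically zero.
    """
    ax = _axis_index(axis)
    x, y, z = grid.coordinates_mm(center=_grid_center_mm(grid))
    pos_m = [np.broadcast_to(c, grid.shape) * 1e-3 for c in (x, y, z)]
    omega_vec = np.zeros(3)
    omega_vec[ax] = omega
    v3 = np.stack([
        omega_vec[1] * pos_m[2] - omega_vec[2] * pos_m[1],
        omega_vec[2] * pos_m[0] - omega_vec[0] * pos_m[2],
        omega_vec[0] * pos_m[1] - omega_vec[1] * pos_m[0],
    ], axis=-1)
    extents = [(grid.nx - 1) * grid.dx, (grid.ny - 1) * grid.dy, (grid.nz - 1) * grid.dz]
    perp = [e for i, e in enumerate(extents) if i != ax]
    if radius_mm is None:
        radius_mm = min(perp) / 2.0
    if length_mm is None:
        length_mm = extents[ax]
    mask3 = _cylinder_mask(grid, radius_mm, length_mm, ax)
    v = np.repeat(v3[:, :, :, None, :], grid.nt, axis=3)
    return VelocityField(grid, v, venc=venc), SegmentationMask(grid, _repeat_phases(mask3, grid.nt).astype(np.uint8))


def make_poiseuille(grid: VoxelGrid, radius_mm: float, length_mm: float, v_max: float,
                    axis="z", venc: float = 1.5) -> tuple[VelocityField, SegmentationMask]:
    """Fully developed laminar pipe flow along `axis`, centred in the grid.

    Axial velocity v(r) = v_max (1 - r^2/R^2) inside the cylinder, zero
    outside. Closed forms over the cylinder V = pi R^2 L:
    EL = 2 pi mu L v_max^2 and KE = rho v_max^2 V / 6.
    """
    ax = _axis_index(axis)
    extents = [(grid.nx - 1) * grid.dx, (grid.ny - 1) * grid.dy, (grid.nz - 1) * grid.dz]
    perp = [e for i, e in enumerate(extents) if i != ax]
    if 2 * radius_mm > min(perp) + 1e-9 or length_mm > extents[ax] + 1e-9:
        raise ValueError("cylinder does not fit in the grid")
    x, y, z = grid.coordinates_mm(center=_grid_center_mm(grid))
    coords = [x, y, z]
    axc = coords.pop(ax)
    r2 = np.broadcast_to(coords[0] ** 2 + coords[1] ** 2, grid.shape)
    inside = r2 <= radius_mm ** 2
    mask3 = inside & np.broadcast_to(np.abs(axc) <= length_mm / 2.0, grid.shape)
    axial = np.where(mask3, v_max * (1.0 - r2 / radius_mm ** 2), 0.0)
    v3 = np.zeros((*grid.shape, 3))
    v3[..., ax] = axial
    v = np.repeat(v3[:, :, :, None, :], grid.nt, axis=3)
    return VelocityField(grid, v, venc=venc), SegmentationMask(grid, _repeat_phases(mask3, grid.nt).astype(np.uint8))


def make_lamb_oseen(grid: VoxelGrid, gamma: float, r_core_mm: float, length_mm: float,
                    axis="z", domain_radius_mm: float | None = None,
                    venc: float = 1.5) -> tuple[VelocityField, SegmentationMask]:
    """Lamb-Oseen (Gaussian-core) line vortex along `axis`.

    Tangential velocity v_theta(r) = (Gamma / 2 pi r)(1 - exp(-r^2/r_c^2))
    with circulation Gamma in m^2/s and core radius r_c in mm. The axial
    vorticity is a positive Gaussian whose per-slice integral is Gamma,
    so over a mask cylinder of length L (radius >= 4 r_c) the volumetric
    vorticity is Gamma * L.
    """
    ax = _axis_index(axis)
    if domain_radius_mm is None:
        domain_radius_mm = 4.0 * r_core_mm
    x, y, z = grid.coordinates_mm(center=_grid_center_mm(grid))
    coords = [x, y, z]
    axc = coords.pop(ax)
    c0 = np.broadcast_to(coords[0], grid.shape) * 1e-3  # m
    c1 = np.broadcast_to(coords[1], grid.shape) * 1e-3
    rc_m = r_core_mm * 1e-3
    r2 = c0 ** 2 + c1 ** 2
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        vth_over_r = np.where(
            r > 1e-12,
            gamma / (2.0 * np.pi * r2) * (1.0 - np.exp(-r2 / rc_m ** 2)),
            gamma / (2.0 * np.pi * rc_m ** 2),  # limit r -> 0
        )
    # v = v_theta * (-sin, cos) in the perpendicular plane = vth_over_r * (-c1, c0)
    perp_axes = [i for i in range(3) if i != ax]
    v3 = np.zeros((*grid.shape, 3))
    v3[..., perp_axes[0]] = -vth_over_r * c1
    v3[..., perp_axes[1]] = vth_over_r * c0
    mask3 = _cylinder_mask(grid, domain_radius_mm, length_mm, ax)
    v = np.repeat(v3[:, :, :, None, :], grid.nt, axis=3)
    return VelocityField(grid, v, venc=venc), SegmentationMask(grid, _repeat_phases(mask3, grid.nt).astype(np.uint8))


def make_beating_ellipsoid_mask(grid: VoxelGrid, semi_axes_ed_mm, semi_axes_es_mm,
                                systole_frames) -> SegmentationMask:
    """Ellipsoidal chamber contracting from ED to ES and relaxing back.

    Semi-axes interpolate linearly in time: over the systolic frames the
    contraction fraction ramps 0 -> 1 (last systolic frame is ES), over
    the diastolic frames it relaxes back towards 0 (phase 0 is ED).
    Per-phase oracle volume: 4/3 pi a b c at the interpolated axes.
    """
    ed = np.asarray(semi_axes_ed_mm, dtype=float)
    es = np.asarray(semi_axes_es_mm, dtype=float)
    nt = grid.nt
    sys_idx = sorted(int(i) for i in systole_frames)
    dia_idx = [t for t in range(nt) if t not in set(sys_idx)]
    frac = np.zeros(nt)
    n_sys, n_dia = len(sys_idx), len(dia_idx)
    for k, t in enumerate(sys_idx):
        frac[t] = k / (n_sys - 1) if n_sys > 1 else 1.0
    for k, t in enumerate(dia_idx):
        frac[t] = 1.0 - (k + 1) / n_dia
    x, y, z = grid.coordinates_mm(center=_grid_center_mm(grid))
    m = np.zeros((*grid.shape, nt), dtype=np.uint8)
    for t in range(nt):
        a, b, c = ed + frac[t] * (es - ed)
        inside = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
        m[..., t] = np.broadcast_to(inside, grid.shape)
    return SegmentationMask(grid, m)


def ellipsoid_volume_ml(semi_axes_mm) -> float:
    """Analytic ellipsoid volume 4/3 pi a b c, in mL."""
    a, b, c = np.asarray(semi_axes_mm, dtype=float)
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def apply_pulsatile(fld: VelocityField, scales) -> VelocityField:
    """Scale each cardiac phase of the field by a per-phase factor."""
    s = np.asarray(scales, dtype=float)
    if s.shape != (fld.grid.nt,):
        raise ValueError("need one scale factor per phase")
    return VelocityField(fld.grid, fld.v * s[None, None, None, :, None], venc=fld.venc)


def add_noise(fld: VelocityField, sigma: float, seed: int | None = None) -> VelocityField:
    """Add i.i.d. zero-mean Gaussian noise (m/s) to every component."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return VelocityField(fld.grid, fld.v.copy(), venc=fld.venc)
    if seed is None:
        raise ValueError("a seed is required when sigma > 0")
    rng = np.random.default_rng(seed)
    return VelocityField(fld.grid, fld.v + rng.normal(0.0, sigma, fld.v.shape), venc=fld.venc)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricPlan:
    """One hemodynamic metric in the cohort model.

    Rest values are Normal(rest_mean, rest_sd) truncated positive; the
    relative rest-to-stress difference (percent) follows
    delta = intercept + slope * VO2max + Normal(0, noise_sd), and
    stress = rest * (1 + delta/100).
    """

    rest_mean: float
    rest_sd: float
    slope: float
    intercept: float
    noise_sd: float

    @classmethod
    def from_planted_correlation(cls, rest_mean, rest_sd, delta_mean, delta_sd,
                                 rho, vo2_mean, vo2_sd) -> "MetricPlan":
        """Choose slope/intercept/noise so that corr(delta, VO2max) = rho
        while delta keeps the requested mean and SD at the population level."""
        slope = rho * delta_sd / vo2_sd
        noise_sd = delta_sd * float(np.sqrt(1.0 - rho ** 2))
        intercept = delta_mean - slope * vo2_mean
        return cls(rest_mean, rest_sd, slope, intercept, noise_sd)


def _default_metrics() -> dict[str, MetricPlan]:
    """Study-condition defaults: single-ventricle cohort group statistics.

    Rest levels (cycle averages): KE 1.8 +- 0.5 mJ, EL 0.9 +- 0.4 mW,
    vorticity_vol 3441 +- 899 mL/s. Relative rest-stress increases of
    88 +- 52 %, 108 +- 49 % and 27 +- 19 % carry inverse correlations of
    -0.83, -0.80 and -0.64 with VO2max (30.2 +- 8.6 mL/kg/min).
    """
    vo2 = (30.2, 8.6)
    return {
        "ke": MetricPlan.from_planted_correlation(1.8, 0.5, 88.0, 52.0, -0.83, *vo2),
        "el": MetricPlan.from_planted_correlation(0.9, 0.4, 108.0, 49.0, -0.80, *vo2),
        "vort": MetricPlan.from_planted_correlation(3441.0, 899.0, 27.0, 19.0, -0.64, *vo2),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Paired rest/stress cohort with a planted VO2max association."""

    n_subjects: int = 10
    vo2max_mean: float = 30.2
    vo2max_sd: float = 8.6
    metrics: dict[str, MetricPlan] = dc_field(default_factory=_default_metrics)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("cohort needs at least 3 subjects")
        if self.vo2max_sd < 0 or any(p.rest_sd < 0 or p.noise_sd < 0 for p in self.metrics.values()):
            raise ValueError("standard deviations must be >= 0")


def _truncated_positive_normal(rng, mean, sd, size):
    vals = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = vals <= 0
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.abs(vals)  # pathological mean/sd only


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a paired rest/stress cohort table.

    Columns: subject_id, vo2max, then <metric>_rest and <metric>_stress
    for every metric in the spec. The planted relative difference is
    recoverable exactly as (stress - rest)/rest * 100.
    """
    rng = np.random.default_rng(spec.seed)
    vo2 = _truncated_positive_normal(rng, spec.vo2max_mean, spec.vo2max_sd, spec.n_subjects)
    out = {"subject_id": [f"S{i + 1:03d}" for i in range(spec.n_subjects)], "vo2max": vo2}
    for name, plan in spec.metrics.items():
        rest = _truncated_positive_normal(rng, plan.rest_mean, plan.rest_sd, spec.n_subjects)
        delta = plan.intercept + plan.slope * vo2 + rng.normal(0.0, plan.noise_sd, spec.n_subjects)
        out[f"{name}_rest"] = rest
        out[f"{name}_stress"] = rest * (1.0 + delta / 100.0)
    return pd.DataFrame(out)
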