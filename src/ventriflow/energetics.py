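"""Voxel-wise intraventricular energetics: KE, viscous energy loss, vorticity.

Per cardiac phase, over the segmented chamber:

* kinetic energy        KE(t)  = sum_{voxels} 1/2 * rho * dV * |v|^2        [mJ]
* viscous loss rate     EL(t)  = mu * sum_{voxels} dV * phi_v               [mW]
* volumetric vorticity  VV(t)  = sum_{voxels} |curl v| * dV                 [mL/s]

phi_v is the Newtonian viscous dissipation function

    phi_v = 1/2 * sum_ij [ (dv_i/dx_j + dv_j/dx_i) - (2/3)(div v) delta_ij ]^2

which reduces to twice the squared strain rate for divergence-free flow;
the divergence term is kept because measured fields are never exactly
solenoidal. Vorticity magnitude is taken voxel-wise before the volume
integral, so counter-rotating structures do not cancel.

Spatial derivatives use central differences wherever both stencil
neighbours lie inside the mask, one-sided differences where only one
does, and zero where neither does: stencils never reach across the
chamber boundary, because velocities outside the segmentation are
undefined. All internal arithmetic is SI; scaling to mJ / mW / (mL/s)
happens only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridError, PhasePartition, SegmentationMask, VelocityField

#: blood density, g/mL (= 1000x kg/m^3)
RHO_BLOOD_G_PER_ML = 1.025
#: dynamic viscosity of blood as a Newtonian fluid, Pa*s
MU_BLOOD_PA_S = 4.0e-3


@dataclass(frozen=True)
class EnergeticsParams:
    """Fluid constants: density in g/mL, dynamic viscosity in Pa*s."""

    rho: float = RHO_BLOOD_G_PER_ML
    mu: float = MU_BLOOD_PA_S

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def rho_si(self) -> float:
        """Density in kg/m^3."""
        return self.rho * 1000.0


@dataclass
class EnergeticsTimeSeries:
    """Per-phase KE (mJ), EL rate (mW) and vorticity_vol (mL/s)."""

    ke_mj: np.ndarray
    el_mw: np.ndarray
    vortvol_ml_s: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ke_mj)
        if len(self.el_mw) != n or len(self.vortvol_ml_s) != n:
            raise ValueError("series length mismatch")


@dataclass
class EnergeticsSummary:
    """Systole/diastole/cycle time-averages, raw and SV-normalised.

    Units: KE mJ, EL mW, vorticity_vol mL/s; normalised variants mJ/mL,
    mW/mL and 1/s respectively. Normalised fields are None until
    :func:`normalize_by_sv` fills them.
    """

    ke_avg_systole: float
    ke_avg_diastole: float
    ke_avg_cycle: float
    el_avg_systole: float
    el_avg_diastole: float
    el_avg_cycle: float
    vortvol_avg_systole: float
    vortvol_avg_diastole: float
    vortvol_avg_cycle: float
    ke_cycle_per_sv: float | None = None
    el_cycle_per_sv: float | None = None
    vortvol_cycle_per_sv: float | None = None

    _ROWS = (
        ("KE_avg systole (mJ)", "ke_avg_systole"),
        ("KE_avg diastole (mJ)", "ke_avg_diastole"),
        ("KE_avg cycle (mJ)", "ke_avg_cycle"),
        ("EL_avg systole (mW)", "el_avg_systole"),
        ("EL_avg diastole (mW)", "el_avg_diastole"),
        ("EL_avg cycle (mW)", "el_avg_cycle"),
        ("Vorticity_vol_avg systole (mL/s)", "vortvol_avg_systole"),
        ("Vorticity_vol_avg diastole (mL/s)", "vortvol_avg_diastole"),
        ("Vorticity_vol_avg cycle (mL/s)", "vortvol_avg_cycle"),
        ("KE_avg cycle/SV (mJ/mL)", "ke_cycle_per_sv"),
        ("EL_avg cycle/SV (mW/mL)", "el_cycle_per_sv"),
        ("Vorticity_vol_avg cycle/SV (1/s)", "vortvol_cycle_per_sv"),
    )

    def as_rows(self) -> dict[str, float | None]:
        return {label: getattr(self, attr) for label, attr in self._ROWS}


def _check_grids(field: VelocityField, mask: SegmentationMask) -> None:
    if mask.grid.shape != field.grid.shape or mask.grid.nt != field.grid.nt:
        raise GridError("mask grid does not match field grid")


def masked_derivative(vol: np.ndarray, mask3: np.ndarray, h: float, axis: int) -> np.ndarray:
    """d(vol)/dx_axis with mask-aware stencils, spacing h in metres.

    Central difference where both neighbours along `axis` are in-mask,
    one-sided where only one is, zero where neither is. Grid edges count
    as out-of-mask.
    """
    vp = np.pad(vol, 1)
    mp = np.pad(mask3, 1)
    core = tuple(slice(1, -1) for _ in range(3))

    def shifted(a, d):
        sl = list(core)
        sl[axis] = slice(1 + d, a.shape[axis] - 1 + d)
        return a[tuple(sl)]

    v_f, v_b = shifted(vp, 1), shifted(vp, -1)
    m_f, m_b = shifted(mp, 1), shifted(mp, -1)
    out = np.zeros_like(vol, dtype=float)
    both = m_f & m_b & mask3
    fwd = m_f & ~m_b & mask3
    bwd = ~m_f & m_b & mask3
    out[both] = (v_f[both] - v_b[both]) / (2.0 * h)
    out[fwd] = (v_f[fwd] - vol[fwd]) / h
    out[bwd] = (vol[bwd] - v_b[bwd]) / h
    return out


def velocity_gradient(field: VelocityField, mask: SegmentationMask, t: int) -> np.ndarray:
    """Velocity-gradient tensor G[..., i, j] = dv_i/dx_j (1/s) at phase t."""
    _check_grids(field, mask)
    m3 = mask.phase(t)
    h_m = [s * 1e-3 for s in field.grid.spacing_mm]
    G = np.zeros((*field.grid.shape, 3, 3))
    for i in range(3):
        vi = field.v[..., t, i]
        for j in range(3):
            G[..., i, j] = masked_derivative(vi, m3, h_m[j], axis=j)
    return G


def kinetic_energy(field: VelocityField, mask: SegmentationMask,
                   params: EnergeticsParams = EnergeticsParams()) -> np.ndarray:
    """Per-phase kinetic energy of the masked blood pool, in mJ.

    KE(t) = sum over in-mask voxels of 1/2 * rho * dV * |v|^2, with the
    voxel mass m = rho * dV.
    """
    _check_grids(field, mask)
    dv_m3 = field.grid.voxel_volume_mm3 * 1e-9
    speed2 = np.sum(field.v ** 2, axis=-1)  # (nx,ny,nz,nt), (m/s)^2
    ke_j = 0.5 * params.rho_si * dv_m3 * np.sum(speed2 * mask.m, axis=(0, 1, 2))
    return ke_j * 1e3


def energy_loss_rate(field: VelocityField, mask: SegmentationMask,
                     params: EnergeticsParams = EnergeticsParams()) -> np.ndarray:
    """Per-phase viscous energy-loss rate, in mW.

    EL(t) = mu * sum_{in-mask voxels} dV * phi_v with the dissipation
    function phi_v defined in the module docstring.
    """
    _check_grids(field, mask)
    dv_m3 = field.grid.voxel_volume_mm3 * 1e-9
    el = np.empty(field.grid.nt)
    for t in range(field.grid.nt):
        G = velocity_gradient(field, mask, t)
        div = np.trace(G, axis1=-2, axis2=-1)
        S = G + np.swapaxes(G, -1, -2)
        S[..., 0, 0] -= (2.0 / 3.0) * div
        S[..., 1, 1] -= (2.0 / 3.0) * div
        S[..., 2, 2] -= (2.0 / 3.0) * div
        phi = 0.5 * np.sum(S ** 2, axis=(-2, -1))
        el[t] = params.mu * dv_m3 * np.sum(phi[mask.phase(t)])
    return el * 1e3


def vorticity_vol(field: VelocityField, mask: SegmentationMask) -> np.ndarray:
    """Per-phase volume-integrated vorticity magnitude, in mL/s.

    omega = curl v per voxel (1/s); the magnitude |omega| is integrated
    over the chamber volume, so the result is direction-blind.
    """
    _check_grids(field, mask)
    dv_ml = field.grid.voxel_volume_ml
    vv = np.empty(field.grid.nt)
    for t in range(field.grid.nt):
        G = velocity_gradient(field, mask, t)
        wx = G[..., 2, 1] - G[..., 1, 2]
        wy = G[..., 0, 2] - G[..., 2, 0]
        wz = G[..., 1, 0] - G[..., 0, 1]
        mag = np.sqrt(wx ** 2 + wy ** 2 + wz ** 2)
        vv[t] = dv_ml * np.sum(mag[mask.phase(t)])
    return vv


def compute_timeseries(field: VelocityField, mask: SegmentationMask,
                       params: EnergeticsParams = EnergeticsParams()) -> EnergeticsTimeSeries:
    """All three per-phase series in one pass."""
    return EnergeticsTimeSeries(
        ke_mj=kinetic_energy(field, mask, params),
        el_mw=energy_loss_rate(field, mask, params),
        vortvol_ml_s=vorticity_vol(field, mask),
    )


def phase_average(series: EnergeticsTimeSeries, partition: PhasePartition) -> EnergeticsSummary:
    """Equal-weight time-averages over systole, diastole and the cycle."""
    nt = len(series.ke_mj)
    partition.validate_for(nt)
    sys_idx = sorted(partition.systole_frames)
    dia_idx = sorted(partition.diastole_frames)

    def avg(a, idx):
        return float(np.mean(np.asarray(a)[idx]))

    return EnergeticsSummary(
        ke_avg_systole=avg(series.ke_mj, sys_idx),
        ke_avg_diastole=avg(series.ke_mj, dia_idx),
        ke_avg_cycle=float(np.mean(series.ke_mj)),
        el_avg_systole=avg(series.el_mw, sys_idx),
        el_avg_diastole=avg(series.el_mw, dia_idx),
        el_avg_cycle=float(np.mean(series.el_mw)),
        vortvol_avg_systole=avg(series.vortvol_ml_s, sys_idx),
        vortvol_avg_diastole=avg(series.vortvol_ml_s, dia_idx),
        vortvol_avg_cycle=float(np.mean(series.vortvol_ml_s)),
    )


def normalize_by_sv(summary: EnergeticsSummary, sv_ml: float) -> EnergeticsSummary:
    """Fill the SV-normalised cycle averages (divide by stroke volume, mL)."""
    if sv_ml <= 0:
        raise ValueError("stroke volume must be positive for normalisation")
    summary.ke_cycle_per_sv = summary.ke_avg_cycle / sv_ml
    summary.el_cycle_per_sv = summary.el_avg_cycle / sv_ml
    summary.vortvol_cycle_per_sv = summary.vortvol_avg_cycle / sv_ml
    return summary
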