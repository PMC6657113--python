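"""Energetics kernels: KE, viscous loss, vorticity, averaging, normalisation.

The brute-force reference implementations here are deliberately naive
per-voxel loops, written independently of the vectorised production
code, and serve as the numerical oracle on small random fields.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventriflow as vf
from ventriflow import phantom
from ventriflow.energetics import EnergeticsParams, EnergeticsTimeSeries

from conftest import poiseuille_grid, random_field_and_mask

MU = 4.0e-3


# ---------------------------------------------------------------------------
# brute-force reference (independent oracle)
# ---------------------------------------------------------------------------

def brute_force_metrics(field, mask, params=EnergeticsParams()):
    """Naive per-voxel loop over phases: KE (mJ), EL (mW), vorticity_vol (mL/s)."""
    g = field.grid
    dv_m3 = g.dx * g.dy * g.dz * 1e-9
    h = (g.dx * 1e-3, g.dy * 1e-3, g.dz * 1e-3)
    ke = np.zeros(g.nt)
    el = np.zeros(g.nt)
    vv = np.zeros(g.nt)

    def deriv(vol, m3, i, j, k, axis):
        idx = [i, j, k]
        lo, hi = list(idx), list(idx)
        lo[axis] -= 1
        hi[axis] += 1
        has_lo = lo[axis] >= 0 and m3[tuple(lo)]
        has_hi = hi[axis] < m3.shape[axis] and m3[tuple(hi)]
        if has_lo and has_hi:
            return (vol[tuple(hi)] - vol[tuple(lo)]) / (2 * h[axis])
        if has_hi:
            return (vol[tuple(hi)] - vol[tuple(idx)]) / h[axis]
        if has_lo:
            return (vol[tuple(idx)] - vol[tuple(lo)]) / h[axis]
        return 0.0

    for t in range(g.nt):
        m3 = mask.m[..., t]
        for i in range(g.nx):
            for j in range(g.ny):
                for k in range(g.nz):
                    if not m3[i, j, k]:
                        continue
                    v = field.v[i, j, k, t]
                    ke[t] += 0.5 * params.rho_si * dv_m3 * float(v @ v)
                    G = np.array([[deriv(field.v[..., t, a], m3, i, j, k, b)
                                   for b in range(3)] for a in range(3)])
                    div = np.trace(G)
                    S = G + G.T - (2.0 / 3.0) * div * np.eye(3)
                    el[t] += params.mu * dv_m3 * 0.5 * np.sum(S ** 2)
                    w = np.array([G[2, 1] - G[1, 2], G[0, 2] - G[2, 0], G[1, 0] - G[0, 1]])
                    vv[t] += np.linalg.norm(w) * dv_m3 * 1e6  # m^3 -> mL
    return ke * 1e3, el * 1e3, vv


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_production_matches_brute_force_on_random_fields(seed):
    field, mask = random_field_and_mask(seed)
    ke_ref, el_ref, vv_ref = brute_force_metrics(field, mask)
    np.testing.assert_allclose(vf.kinetic_energy(field, mask), ke_ref, rtol=1e-10)
    np.testing.assert_allclose(vf.energy_loss_rate(field, mask), el_ref, rtol=1e-10)
    np.testing.assert_allclose(vf.vorticity_vol(field, mask), vv_ref, rtol=1e-10)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

class TestVelocityGradient:
    def test_exact_on_linear_shear(self):
        # v_x = a*y: central AND one-sided stencils are exact on linear fields
        grid = vf.VoxelGrid(8, 8, 8, 1.0, 2.0, 1.0, nt=1)
        a = 3.0
        y_m = np.arange(8)[None, :, None] * 2.0e-3
        v = np.zeros((8, 8, 8, 1, 3))
        v[..., 0, 0] = y_m * a
        field = vf.VelocityField(grid, v)
        mask = vf.SegmentationMask(grid, np.ones((8, 8, 8, 1), dtype=np.uint8))
        G = vf.velocity_gradient(field, mask, 0)
        np.testing.assert_allclose(G[..., 0, 1], a, rtol=1e-12)
        assert np.all(G[..., 1, :] == 0) and np.all(G[..., 2, :] == 0)

    def test_poiseuille_wall_shear(self):
        # max |dv_z/dr| = 2 v_max / R at the wall
        fld, mask = phantom.make_poiseuille(poiseuille_grid(64), 10.0, 50.0, 1.0)
        G = vf.velocity_gradient(fld, mask, 0)
        shear = np.sqrt(G[..., 2, 0] ** 2 + G[..., 2, 1] ** 2)
        assert shear.max() == pytest.approx(2 * 1.0 / 0.01, rel=0.05)

    def test_stencil_never_reaches_outside_mask(self):
        # voxel with an out-of-mask neighbour must ignore that neighbour
        grid = vf.VoxelGrid(3, 3, 3, 1, 1, 1, nt=1)
        v = np.zeros((3, 3, 3, 1, 3))
        v[..., 0] = 100.0  # constant inside; value outside mask is irrelevant
        m = np.zeros((3, 3, 3, 1), dtype=np.uint8)
        m[1, :, :] = 1
        field = vf.VelocityField(grid, v)
        field.v[0] = -999.0  # garbage outside the mask
        field.v[2] = 999.0
        G = vf.velocity_gradient(field, vf.SegmentationMask(grid, m), 0)
        assert np.all(G[1] == 0.0)


# ---------------------------------------------------------------------------
# integral metrics
# ---------------------------------------------------------------------------

class TestKineticEnergy:
    def test_quadratic_homogeneity(self):
        field, mask = random_field_and_mask(4)
        ke1 = vf.kinetic_energy(field, mask)
        field2 = vf.VelocityField(field.grid, field.v * 2.0, venc=field.venc)
        np.testing.assert_allclose(vf.kinetic_energy(field2, mask), 4.0 * ke1, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        field, _ = random_field_and_mask(0)
        _, mask = random_field_and_mask(0, shape=(6, 6, 6))
        with pytest.raises(vf.grid.GridError):
            vf.kinetic_energy(field, mask)


class TestScalingAndAdditivity:
    @pytest.mark.parametrize("k", [-1.0, 0.5, 3.0])
    def test_homogeneity_of_all_metrics(self, k):
        field, mask = random_field_and_mask(5)
        scaled = vf.VelocityField(field.grid, field.v * k, venc=field.venc)
        np.testing.assert_allclose(vf.kinetic_energy(scaled, mask),
                                   k ** 2 * vf.kinetic_energy(field, mask), rtol=1e-10)
        np.testing.assert_allclose(vf.energy_loss_rate(scaled, mask),
                                   k ** 2 * vf.energy_loss_rate(field, mask), rtol=1e-10)
        np.testing.assert_allclose(vf.vorticity_vol(scaled, mask),
                                   abs(k) * vf.vorticity_vol(field, mask), rtol=1e-10)

    def test_mask_additivity_over_disjoint_split(self):
        field, mask = random_field_and_mask(6)
        rng = np.random.default_rng(6)
        split = rng.random(mask.m.shape) < 0.5
        m_a = vf.SegmentationMask(field.grid, (mask.m & split).astype(np.uint8))
        m_b = vf.SegmentationMask(field.grid, (mask.m & ~split).astype(np.uint8))
        # KE and vorticity_vol are per-voxel sums -> exactly additive;
        # EL uses mask-dependent stencils, so additivity holds per-voxel
        # only when gradients are evaluated on the union mask
        ke = vf.kinetic_energy(field, mask)
        np.testing.assert_allclose(
            vf.kinetic_energy(field, m_a) + vf.kinetic_energy(field, m_b), ke, rtol=1e-10)

    def test_counter_rotating_cores_do_not_cancel(self):
        # two solid-body cores with opposite omega: |omega| integral adds
        grid = vf.VoxelGrid(40, 20, 20, 1.0, 1.0, 1.0, nt=1)
        x, y, z = grid.coordinates_mm()
        v = np.zeros((40, 20, 20, 1, 3))
        omega = 8.0
        for cx, sign in ((9.5, 1.0), (29.5, -1.0)):
            r2 = (x - cx) ** 2 + (y - 9.5) ** 2
            core = np.broadcast_to(r2 <= 36.0, grid.shape)
            v[..., 0, 0] -= np.where(core, sign * omega * (y - 9.5) * 1e-3, 0.0)
            v[..., 0, 1] += np.where(core, sign * omega * (x - cx) * 1e-3, 0.0)
        field = vf.VelocityField(grid, v)
        half = np.zeros((40, 20, 20, 1), dtype=np.uint8)
        half[:16, ...] = 1  # interior of first core only
        core1 = np.zeros_like(half)
        core1[np.broadcast_to((x - 9.5) ** 2 + (y - 9.5) ** 2 <= 16.0, grid.shape)[..., None]] = 1
        both = np.zeros_like(half)
        for cx in (9.5, 29.5):
            both[np.broadcast_to((x - cx) ** 2 + (y - 9.5) ** 2 <= 16.0, grid.shape)[..., None]] = 1
        vv_one = vf.vorticity_vol(field, vf.SegmentationMask(grid, core1))[0]
        vv_both = vf.vorticity_vol(field, vf.SegmentationMask(grid, both))[0]
        assert vv_both == pytest.approx(2.0 * vv_one, rel=1e-10)
        assert vv_one > 0


# ---------------------------------------------------------------------------
# averaging and normalisation
# ---------------------------------------------------------------------------

class TestPhaseAverage:
    def test_hand_computed_example(self):
        series = EnergeticsTimeSeries(
            ke_mj=np.array([2.0, 4.0, 1.0, 1.0, 1.0, 1.0]),
            el_mw=np.zeros(6), vortvol_ml_s=np.zeros(6))
        part = vf.PhasePartition([0, 1], [2, 3, 4, 5])
        s = vf.phase_average(series, part)
        assert s.ke_avg_systole == pytest.approx(3.0)
        assert s.ke_avg_diastole == pytest.approx(1.0)
        assert s.ke_avg_cycle == pytest.approx(10.0 / 6.0)

    def test_constant_series_all_averages_equal(self):
        series = EnergeticsTimeSeries(np.full(8, 2.5), np.full(8, 1.5), np.full(8, 900.0))
        s = vf.phase_average(series, vf.PhasePartition(range(3), range(3, 8)))
        assert s.ke_avg_systole == s.ke_avg_diastole == s.ke_avg_cycle == 2.5
        assert s.vortvol_avg_cycle == 900.0

    def test_cycle_average_lies_between_systole_and_diastole(self):
        rng = np.random.default_rng(9)
        series = EnergeticsTimeSeries(rng.random(10), rng.random(10), rng.random(10))
        s = vf.phase_average(series, vf.PhasePartition(range(4), range(4, 10)))
        lo, hi = sorted((s.ke_avg_systole, s.ke_avg_diastole))
        assert lo - 1e-12 <= s.ke_avg_cycle <= hi + 1e-12

    def test_pulsatile_phantom_quadratic_scaling(self, small_grid):
        grid = vf.VoxelGrid(10, 10, 10, 2, 2, 2, nt=4)
        base, mask = phantom.make_uniform(grid, (1.0, 0.0, 0.0))
        scales = np.array([1.0, 0.5, 0.25, 0.75])
        fld = phantom.apply_pulsatile(base, scales)
        ke0 = vf.kinetic_energy(base, mask)[0]
        series = EnergeticsTimeSeries(vf.kinetic_energy(fld, mask), np.zeros(4), np.zeros(4))
        s = vf.phase_average(series, vf.PhasePartition([0, 1], [2, 3]))
        assert s.ke_avg_systole == pytest.approx(ke0 * np.mean(scales[:2] ** 2), rel=1e-12)
        assert s.ke_avg_cycle == pytest.approx(ke0 * np.mean(scales ** 2), rel=1e-12)

    def test_partition_not_covering_nt_rejected(self):
        series = EnergeticsTimeSeries(np.ones(6), np.ones(6), np.ones(6))
        with pytest.raises(vf.grid.GridError):
            vf.phase_average(series, vf.PhasePartition([0, 1], [2, 3]))


class TestNormalizeBySv:
    def test_simple_division(self):
        series = EnergeticsTimeSeries(np.full(2, 3.3), np.full(2, 1.9), np.full(2, 4400.0))
        s = vf.phase_average(series, vf.PhasePartition([0], [1]))
        vf.normalize_by_sv(s, 100.0)
        assert s.ke_cycle_per_sv == pytest.approx(0.033)
        assert s.vortvol_cycle_per_sv == pytest.approx(44.0)

    def test_doubling_sv_halves_values(self):
        series = EnergeticsTimeSeries(np.full(2, 3.0), np.full(2, 1.0), np.full(2, 4000.0))
        a = vf.normalize_by_sv(vf.phase_average(series, vf.PhasePartition([0], [1])), 50.0)
        b = vf.normalize_by_sv(vf.phase_average(series, vf.PhasePartition([0], [1])), 100.0)
        assert a.ke_cycle_per_sv == pytest.approx(2.0 * b.ke_cycle_per_sv)

    def test_nonpositive_sv_rejected(self):
        series = EnergeticsTimeSeries(np.ones(2), np.ones(2), np.ones(2))
        s = vf.phase_average(series, vf.PhasePartition([0], [1]))
        with pytest.raises(ValueError):
            vf.normalize_by_sv(s, 0.0)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 1000))
def test_metrics_are_nonnegative(seed):
    field, mask = random_field_and_mask(seed, shape=(5, 5, 5), nt=1)
    assert vf.kinetic_energy(field, mask)[0] >= 0
    assert vf.energy_loss_rate(field, mask)[0] >= 0
    assert vf.vorticity_vol(field, mask)[0] >= 0


def test_poiseuille_el_error_strictly_decreases_under_refinement():
    exact = 2 * np.pi * MU * 0.05 * 1e3
    errs = []
    for n in (32, 64, 128):
        fld, mask = phantom.make_poiseuille(poiseuille_grid(n), 10.0, 50.0, 1.0)
        el = vf.energy_loss_rate(fld, mask)[0]
        errs.append(abs(el - exact) / exact)
    assert errs[0] > errs[1] > errs[2]
    assert errs[1] < 0.05
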