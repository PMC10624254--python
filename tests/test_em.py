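"""Birdcage sources, field extraction, normalization and SAR."""

import numpy as np
import pytest

import voxdosim.em as em
from voxdosim.em import (
    CoilModel,
    EMFields,
    b1_minus,
    b1_plus,
    build_birdcage_sources,
    mass_averaged_sar,
    normalize_fields,
    pointwise_sar,
    region_average_sar,
    required_b1,
)
from voxdosim.fdtd import MU0, solve_plane_wave_1d
from voxdosim.tissues import default_tissue_table
from voxdosim.volume import LabelVolume

SMALL_COIL = CoilModel(coil_diameter_mm=120.0, coil_length_mm=80.0,
                       shield_diameter_mm=150.0)


@pytest.fixture(scope="module")
def empty_coil_fields(tissue_table):
    """Unloaded small birdcage solved at 5 mm (shared across tests)."""
    empty = LabelVolume(np.zeros((3, 3, 3), dtype=np.int32), (5.0,) * 3,
                        labels={})
    return em.fdtd_solve(empty, tissue_table, SMALL_COIL,
                         settings=em.FDTDSettings(max_periods=60))


class TestCoilSources:
    def test_rung_phasors_sum_to_zero(self):
        coil = CoilModel()
        assert abs(coil.rung_phasors().sum()) < 1e-12

    def test_mode_one_cosine_amplitude_pattern(self):
        coil = CoilModel()
        theta = 2 * np.pi * np.arange(16) / 16
        # instantaneous currents at t=0 follow the mode-1 cos(theta) pattern
        assert np.allclose(np.real(coil.rung_phasors()), np.cos(theta))

    def test_rotation_by_one_rung_multiplies_by_unit_phase(self):
        coil = CoilModel()
        ph = coil.rung_phasors()
        rotated = np.roll(ph, -1)
        assert np.allclose(rotated, ph * np.exp(-1j * 2 * np.pi / 16))

    def test_bilinear_weights_conserve_current(self):
        si, sj, sw, sp, k0, k1 = build_birdcage_sources(
            SMALL_COIL, (40, 40, 40), 5.0)
        # each rung spreads unit current over <=4 edge columns
        total = {}
        for w, p in zip(sw, sp):
            total[p] = total.get(p, 0.0) + w
        assert all(abs(t - 1.0) < 1e-12 for t in total.values())
        assert k1 - k0 == round(SMALL_COIL.coil_length_mm / 5.0)

    def test_coil_must_fit_in_domain(self):
        with pytest.raises(ValueError, match="fit"):
            build_birdcage_sources(CoilModel(), (20, 20, 20), 4.0)

    def test_shield_must_exceed_coil(self):
        with pytest.raises(ValueError, match="shield"):
            CoilModel(coil_diameter_mm=305.0, shield_diameter_mm=300.0)


class TestB1:
    def _fields(self, B):
        E = np.zeros(B.shape, dtype=complex)
        return EMFields(E=E, B=B, spacing_mm=1.0, origin_mm=(0, 0, 0),
                        frequency_hz=297.2e6, coil_center_index=(0, 0, 0))

    def test_zero_field(self):
        f = self._fields(np.zeros((2, 2, 2, 3), dtype=complex))
        assert np.all(b1_plus(f) == 0)

    def test_pure_circular_polarization(self):
        B0 = 3.2e-6
        B = np.zeros((1, 1, 1, 3), dtype=complex)
        B[..., 0] = B0
        B[..., 1] = -1j * B0
        f = self._fields(B)
        assert abs(b1_plus(f)[0, 0, 0]) == pytest.approx(B0)
        assert abs(b1_minus(f)[0, 0, 0]) == pytest.approx(0.0, abs=1e-20)

    def test_linear_polarization_splits_evenly(self):
        B0 = 2.0e-6
        B = np.zeros((1, 1, 1, 3), dtype=complex)
        B[..., 0] = B0
        f = self._fields(B)
        assert abs(b1_plus(f)[0, 0, 0]) == pytest.approx(B0 / 2)
        assert abs(b1_minus(f)[0, 0, 0]) == pytest.approx(B0 / 2)


class TestRequiredB1:
    def test_90_degree_3ms_is_about_2_uT(self):
        b1 = required_b1(np.pi / 2, 3e-3)
        assert b1 == pytest.approx(1.957e-6, rel=1e-3)
        assert round(b1 * 1e6) == 2  # the normalization target, 1 sig fig

    def test_linear_in_flip_angle(self):
        assert required_b1(np.pi, 3e-3) == pytest.approx(3.914e-6, rel=1e-3)

    def test_inverse_in_duration(self):
        assert required_b1(np.pi / 2, 6e-3) == pytest.approx(0.979e-6, rel=1e-3)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            required_b1(np.pi / 2, 0.0)


class TestPointwiseSar:
    def test_zero_field_zero_sar(self):
        E = np.zeros((3, 3, 3, 3), dtype=complex)
        sar = pointwise_sar(E, np.ones((3, 3, 3)), np.full((3, 3, 3), 1000.0),
                            np.ones((3, 3, 3), bool))
        assert np.all(sar == 0)

    def test_direct_substitution(self):
        E = np.zeros((1, 1, 1, 3), dtype=complex)
        E[..., 0] = 1.0
        sar = pointwise_sar(E, np.full((1, 1, 1), 2.0),
                            np.full((1, 1, 1), 1000.0),
                            np.ones((1, 1, 1), bool))
        assert sar[0, 0, 0] == pytest.approx(1.0e-3)

    def test_quadratic_in_field(self, rng):
        E = (rng.standard_normal((4, 4, 4, 3))
             + 1j * rng.standard_normal((4, 4, 4, 3)))
        sigma = rng.random((4, 4, 4)) + 0.1
        rho = np.full((4, 4, 4), 1050.0)
        t = np.ones((4, 4, 4), bool)
        assert np.allclose(pointwise_sar(2 * E, sigma, rho, t),
                           4 * pointwise_sar(E, sigma, rho, t), rtol=1e-12)

    def test_total_power_identity(self, rng):
        E = (rng.standard_normal((5, 5, 5, 3))
             + 1j * rng.standard_normal((5, 5, 5, 3)))
        sigma = rng.random((5, 5, 5))
        rho = 900.0 + 300.0 * rng.random((5, 5, 5))
        t = np.ones((5, 5, 5), bool)
        sar = pointwise_sar(E, sigma, rho, t)
        e2 = np.sum(np.abs(E) ** 2, axis=-1)
        v = 1.0  # arbitrary common voxel volume cancels
        assert np.sum(sar * rho * v) == pytest.approx(
            np.sum(0.5 * sigma * e2 * v), rel=1e-12)

    def test_air_excluded(self):
        E = np.ones((2, 2, 2, 3), dtype=complex)
        tissue = np.zeros((2, 2, 2), bool)
        tissue[0] = True
        sar = pointwise_sar(E, np.ones((2, 2, 2)), np.full((2, 2, 2), 1000.0),
                            tissue)
        assert np.all(sar[1] == 0)


def brute_force_mass_averaged(sar, rho, spacing, tissue, target=10.0):
    """Exhaustive centered-cube search (independent oracle)."""
    n = sar.shape
    vox = np.where(tissue, rho * np.prod(np.broadcast_to(
        np.asarray(spacing, float), (3,))) * 1e-9 * 1e3, 0.0)
    out = np.full(n, np.nan)
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                if not tissue[i, j, k]:
                    continue
                m_prev = vox[i, j, k]
                s_prev = sar[i, j, k] * m_prev
                if m_prev >= target:
                    out[i, j, k] = sar[i, j, k]
                    continue
                wmax = min(i, n[0] - 1 - i, j, n[1] - 1 - j, k, n[2] - 1 - k)
                for w in range(1, wmax + 1):
                    m = s = 0.0
                    for a in range(i - w, i + w + 1):
                        for b in range(j - w, j + w + 1):
                            for c in range(k - w, k + w + 1):
                                m += vox[a, b, c]
                                s += sar[a, b, c] * vox[a, b, c]
                    if m >= target:
                        f = (target - m_prev) / (m - m_prev)
                        out[i, j, k] = (s_prev + f * (s - s_prev)) / target
                        break
                    m_prev, s_prev = m, s
    return out


class TestMassAveragedSar:
    def test_uniform_sar_is_unchanged(self):
        n = 11
        sar = np.full((n, n, n), 2.5)
        rho = np.full((n, n, n), 1050.0)
        t = np.ones((n, n, n), bool)
        out, mx = mass_averaged_sar(sar, rho, 10.0, t)  # 1.05 g voxels
        valid = np.isfinite(out)
        assert np.allclose(out[valid], 2.5, rtol=1e-12)
        assert mx == pytest.approx(2.5, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        n = 12
        sar = rng.random((n, n, n))
        rho = np.full((n, n, n), 1050.0)
        tissue = rng.random((n, n, n)) > 0.25
        out, _ = mass_averaged_sar(sar, rho, 10.0, tissue)
        oracle = brute_force_mass_averaged(sar, rho, 10.0, tissue)
        resolvable = np.isfinite(oracle)
        assert np.allclose(out[resolvable], oracle[resolvable],
                           rtol=1e-12, atol=1e-15)

    def test_single_hot_voxel_mass_dilution(self):
        n = 15
        sar = np.zeros((n, n, n))
        rho = np.full((n, n, n), 1000.0)
        t = np.ones((n, n, n), bool)
        sp = 10.0  # voxel mass 1 g
        s0 = 7.0
        sar[7, 7, 7] = s0
        out, mx = mass_averaged_sar(sar, rho, sp, t)
        # the hot voxel's 1 g dilutes into the 10 g cube
        assert mx == pytest.approx(s0 * 1.0 / 10.0, rel=1e-9)

    def test_contraction_property(self, rng):
        n = 13
        sar = rng.random((n, n, n)) * 5
        rho = np.full((n, n, n), 1050.0)
        t = np.ones((n, n, n), bool)
        out, mx = mass_averaged_sar(sar, rho, 10.0, t)
        assert mx <= sar.max() + 1e-12

    def test_light_phantom_rejected(self):
        sar = np.ones((4, 4, 4))
        rho = np.full((4, 4, 4), 1000.0)
        t = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="below the 10 g"):
            mass_averaged_sar(sar, rho, 4.0, t)  # 64 voxels x 64 mg = 4.1 g


class TestRegionAverage:
    def test_uniform(self):
        sar = np.full((4, 4, 4), 3.0)
        rho = np.full((4, 4, 4), 1000.0)
        assert region_average_sar(sar, rho, np.ones((4, 4, 4), bool)) == 3.0

    def test_two_equal_mass_halves(self):
        sar = np.empty((4, 4, 4))
        sar[:2] = 1.0
        sar[2:] = 3.0
        rho = np.full((4, 4, 4), 1000.0)
        assert region_average_sar(sar, rho, np.ones((4, 4, 4), bool)) == 2.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="no tissue"):
            region_average_sar(np.ones((3, 3, 3)), np.ones((3, 3, 3)),
                               np.zeros((3, 3, 3), bool))


class TestNormalization:
    def test_scale_contract(self, empty_coil_fields):
        f = empty_coil_fields
        target = 2.0e-6
        fn, scale = normalize_fields(f, target)
        c = fn.coil_center_index
        assert abs(abs(b1_plus(fn)[c]) - target) < 1e-15
        b1_before = abs(b1_plus(f)[f.coil_center_index])
        assert scale == pytest.approx(target / b1_before)

    def test_already_at_target_gives_unity(self, empty_coil_fields):
        f, _ = normalize_fields(empty_coil_fields, 2.0e-6)
        _, scale = normalize_fields(f, 2.0e-6)
        assert scale == pytest.approx(1.0)

    def test_sar_scales_quadratically(self, empty_coil_fields, rng):
        f = empty_coil_fields
        f2, scale = normalize_fields(f, 2 * abs(
            b1_plus(f)[f.coil_center_index]))
        assert scale == pytest.approx(2.0)
        sigma = np.full(f.shape, 0.5)
        rho = np.full(f.shape, 1000.0)
        t = np.ones(f.shape, bool)
        assert np.allclose(pointwise_sar(f2.E, sigma, rho, t),
                           4 * pointwise_sar(f.E, sigma, rho, t), rtol=1e-12)


class TestFdtdPhysics:
    def test_empty_coil_center_is_circularly_polarized(self, empty_coil_fields):
        f = empty_coil_fields
        c = f.coil_center_index
        b1p = abs(b1_plus(f)[c])
        b1m = abs(b1_minus(f)[c])
        assert b1p > 0
        assert b1m / b1p < 0.05
        assert f.convergence["converged"]

    def test_plane_wave_skin_depth(self):
        f = 297.2e6
        omega = 2 * np.pi * f
        sigma_c = 1.0
        delta = np.sqrt(2.0 / (omega * MU0 * sigma_c))
        dz = delta / 12.0  # >= 10 cells per skin depth
        n_vac = 60
        n_cond = int(10 * delta / dz)
        n = n_vac + n_cond
        eps = np.ones(n)
        sig = np.zeros(n)
        sig[n_vac:] = sigma_c
        ph = solve_plane_wave_1d(eps, sig, dz, f, src_cell=10, n_periods=60)
        z = (np.arange(n) - n_vac) * dz
        sel = (z > delta) & (z < 3 * delta)
        slope = np.polyfit(z[sel], np.log(np.abs(ph[sel])), 1)[0]
        assert abs(-slope - 1.0 / delta) * delta < 0.05

    def test_source_scaling_is_linear_in_fields(self, tissue_table):
        """Doubling all impressed currents doubles E (and quadruples SAR)."""
        from voxdosim.fdtd import run_birdcage_fdtd
        coil = CoilModel(coil_diameter_mm=80.0, coil_length_mm=48.0,
                         shield_diameter_mm=104.0)
        d_mm = 8.0
        n = 2 * int(np.ceil(104.0 / 2 / 8.0 + 3)) + 1
        nz = 30
        eps = np.ones((n, n, nz))
        sig = np.zeros((n, n, nz))
        pec = np.zeros((n, n, nz), bool)
        srcs = build_birdcage_sources(coil, (n, n, nz), d_mm)
        si, sj, sw, sp, k0, k1 = srcs
        kwargs = dict(absorber_cells=6, min_periods=12, max_periods=40,
                      ramp_periods=2.0)
        r1 = run_birdcage_fdtd(eps, sig, pec, d_mm * 1e-3, 297.2e6,
                               si, sj, sw, sp, k0, k1, **kwargs)
        r2 = run_birdcage_fdtd(eps, sig, pec, d_mm * 1e-3, 297.2e6,
                               si, sj, 2.0 * sw, sp, k0, k1, **kwargs)
        big = np.abs(r1.E) > np.abs(r1.E).max() * 1e-6
        assert np.allclose(r2.E[big], 2.0 * r1.E[big], rtol=1e-9)
        sar1 = np.sum(np.abs(r1.E) ** 2, axis=-1)
        sar2 = np.sum(np.abs(r2.E) ** 2, axis=-1)
        big3 = sar1 > sar1.max() * 1e-9
        assert np.allclose(sar2[big3], 4.0 * sar1[big3], rtol=1e-9)

    def test_zero_sources_give_zero_fields(self):
        from voxdosim.fdtd import run_birdcage_fdtd
        n = 12
        eps = np.ones((n, n, n))
        sig = np.zeros((n, n, n))
        pec = np.zeros((n, n, n), bool)
        res = run_birdcage_fdtd(
            eps, sig, pec, 8e-3, 297.2e6,
            np.zeros(0, dtype=int), np.zeros(0, dtype=int),
            np.zeros(0), np.zeros(0), 2, 8,
            absorber_cells=2, min_periods=2, max_periods=4)
        assert np.all(res.E == 0)
        assert np.all(res.H == 0)
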