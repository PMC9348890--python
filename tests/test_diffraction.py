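import numpy as np
import pytest

import cxdisim as cx
from cxdisim.diffraction import (
    build_volume,
    default_n_grid,
    expected_photons,
    multi_particle_pattern,
    pattern_to_photons,
    slice_pattern,
    structure_factor_direct,
)
from cxdisim.rotation import quat_to_matrix, random_quaternion


@pytest.fixture
def q_grid():
    rng = np.random.default_rng(2)
    return rng.uniform(-0.5, 0.5, size=(200, 3))


class TestStructureFactorDirect:
    def test_single_carbon_is_real_form_factor(self, q_grid):
        p = cx.Particle(
            positions=np.zeros((1, 3)), species=np.array(["C"], dtype=object), registry={}
        )
        F = structure_factor_direct(p, q_grid)
        np.testing.assert_allclose(F.imag, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            F.real, cx.form_factor("C", np.linalg.norm(q_grid, axis=1))
        )

    def test_two_atom_cosine_fringes_and_zeros(self):
        d = 8.0
        p = cx.make_fixture("two_atom", d=d)
        qx = np.linspace(0.0, 1.2, 4001)
        q = np.zeros((len(qx), 3))
        q[:, 0] = qx
        I = np.abs(structure_factor_direct(p, q)) ** 2
        f = cx.form_factor("C", qx)
        np.testing.assert_allclose(I, 4 * f**2 * np.cos(qx * d / 2) ** 2, rtol=1e-10)
        # zeros at odd multiples of pi/d
        for m in (1, 3):
            i = np.argmin(np.abs(qx - m * np.pi / d))
            assert I[i] < 1e-6 * I[0]

    def test_translation_leaves_intensity_invariant(self, q_grid, coil40):
        moved = coil40.copy(positions=coil40.positions + np.array([5.0, -3.0, 11.0]))
        I1 = np.abs(structure_factor_direct(coil40, q_grid)) ** 2
        I2 = np.abs(structure_factor_direct(moved, q_grid)) ** 2
        np.testing.assert_allclose(I1, I2, rtol=1e-9)

    def test_solvent_points_contribute(self):
        ball = cx.make_fixture("ball", radius=10.0, density=0.3, voxel=1.5)
        F0 = structure_factor_direct(ball, np.zeros((1, 3)))[0]
        assert F0.real == pytest.approx(ball.solvent_amplitudes.sum())


class TestBuildVolume:
    def test_values_match_direct_summation(self, coil40):
        vol = build_volume(coil40, q_max=0.4, n_grid=15)
        axis = np.linspace(-0.4, 0.4, 15)
        rng = np.random.default_rng(1)
        # slab-shaped batches reproduce the builder's code path bitwise
        for i in rng.integers(0, 15, size=3):
            qy, qz = np.meshgrid(axis, axis, indexing="ij")
            plane = np.column_stack(
                [np.full(225, axis[i]), qy.ravel(), qz.ravel()]
            )
            F = structure_factor_direct(coil40, plane)
            np.testing.assert_array_equal(
                vol.grid[i], (F.real**2 + F.imag**2).reshape(15, 15)
            )
        # and arbitrary single points agree to floating-point rounding
        for _ in range(20):
            i, j, k = rng.integers(0, 15, size=3)
            F = structure_factor_direct(
                coil40, np.array([[axis[i], axis[j], axis[k]]])
            )[0]
            assert vol.grid[i, j, k] == pytest.approx(
                F.real**2 + F.imag**2, rel=1e-12
            )

    def test_friedel_symmetry(self, coil40):
        vol = build_volume(coil40, q_max=0.4, n_grid=13)
        flipped = vol.grid[::-1, ::-1, ::-1]
        np.testing.assert_allclose(vol.grid, flipped, rtol=1e-6)

    def test_central_voxel_equals_total_electrons_squared(self):
        p = cx.Particle(
            positions=np.array([[0.0, 0, 0], [3.0, 0, 0], [-3.0, 1, 0]]),
            species=np.array(["C", "C", "C"], dtype=object),
            registry={},
        )
        vol = build_volume(p, q_max=0.3, n_grid=9)
        f0 = cx.form_factor("C", 0.0)
        assert vol.grid[4, 4, 4] == pytest.approx((3 * f0) ** 2, rel=1e-9)

    def test_invalid_grid_rejected(self, coil40):
        with pytest.raises(ValueError):
            build_volume(coil40, q_max=0.3, n_grid=10)

    def test_hdf5_roundtrip(self, coil40, tmp_path):
        vol = build_volume(coil40, q_max=0.3, n_grid=9)
        vol.save(tmp_path / "vol.h5")
        back = cx.DiffractionVolume.load(tmp_path / "vol.h5")
        np.testing.assert_array_equal(back.grid, vol.grid)
        assert back.q_max == vol.q_max


class TestSlicePattern:
    def test_identity_orientation_at_grid_nodes(self, coil40):
        # construct pixel maps whose q-vectors coincide with volume nodes
        vol = build_volume(coil40, q_max=0.4, n_grid=21)
        axis = np.linspace(-0.4, 0.4, 21)
        qv = np.zeros((21, 21, 3))
        qv[..., 0], qv[..., 1] = np.meshgrid(axis, axis, indexing="ij")
        maps = cx.PixelMaps(
            q_vectors=qv,
            q_mag=np.linalg.norm(qv, axis=-1),
            solid_angle=np.full((21, 21), 1e-8),
            polarization=np.ones((21, 21)),
            mask=np.ones((21, 21), dtype=bool),
            wavelength_A=2.0,
        )
        pattern = slice_pattern(vol, np.array([1.0, 0, 0, 0]), maps)
        np.testing.assert_allclose(pattern, vol.grid[:, :, 10], rtol=1e-12)

    def test_oracle_agreement_at_default_oversampling(self, coil40, small_detector):
        geom, maps = small_detector
        q_max = 1.02 * maps.q_mag.max()
        vol = build_volume(coil40, q_max, n_grid=default_n_grid(coil40, q_max, 4))
        rng = np.random.default_rng(7)
        for _ in range(3):
            quat = random_quaternion(rng)
            sliced = slice_pattern(vol, quat, maps)
            R = quat_to_matrix(quat)
            qr = maps.q_vectors.reshape(-1, 3) @ R
            direct = np.abs(structure_factor_direct(coil40, qr)) ** 2
            rel_rms = np.sqrt(np.mean((sliced.ravel() - direct) ** 2)) / np.sqrt(
                np.mean(direct**2)
            )
            assert rel_rms <= 0.01

    def test_quaternion_double_cover(self, coil40, small_detector):
        _, maps = small_detector
        vol = build_volume(coil40, 1.02 * maps.q_mag.max(), n_grid=31)
        quat = random_quaternion(np.random.default_rng(3))
        p1 = slice_pattern(vol, quat, maps)
        p2 = slice_pattern(vol, -quat, maps)
        np.testing.assert_array_equal(p1, p2)

    def test_all_pixels_outside_volume_errors(self, coil40, small_detector):
        _, maps = small_detector
        vol = build_volume(coil40, q_max=1e-6, n_grid=9)
        with pytest.raises(ValueError):
            slice_pattern(vol, np.array([1.0, 0, 0, 0]), maps)

    def test_rotational_invariance_of_isotropic_profile(self, small_detector):
        _, maps = small_detector
        ball = cx.make_fixture("ball", radius=8.0, density=0.3, voxel=1.5)
        q_max = 1.02 * maps.q_mag.max()
        vol = build_volume(ball, q_max, n_grid=default_n_grid(ball, q_max, 4))
        rng = np.random.default_rng(5)
        profiles = []
        for _ in range(2):
            pattern = slice_pattern(vol, random_quaternion(rng), maps)
            profiles.append(cx.radial_profile(pattern, maps, n_bins=30)[1])
        scale = np.nanmax(profiles[0])
        np.testing.assert_allclose(profiles[0] / scale, profiles[1] / scale, atol=0.01)


class TestMultiParticle:
    def test_single_particle_reduces_to_slice(self, coil40, small_detector):
        _, maps = small_detector
        vol = build_volume(coil40, 1.02 * maps.q_mag.max(), n_grid=31)
        quat = random_quaternion(np.random.default_rng(0))
        p1 = multi_particle_pattern([(vol, quat, np.zeros(3))], maps)
        p2 = slice_pattern(vol, quat, maps)
        np.testing.assert_array_equal(p1, p2)

    def test_two_point_scatterers_match_in_particle_oracle(self, small_detector):
        # two single-atom "particles" separated by d == one two-atom particle
        _, maps = small_detector
        d = 6.0
        single = cx.Particle(
            positions=np.zeros((1, 3)), species=np.array(["C"], dtype=object), registry={}
        )
        ident = np.array([1.0, 0, 0, 0])
        pattern = multi_particle_pattern(
            [
                (single, ident, np.array([-d / 2, 0, 0])),
                (single, ident, np.array([d / 2, 0, 0])),
            ],
            maps,
        )
        two = cx.make_fixture("two_atom", d=d)
        oracle = np.abs(
            structure_factor_direct(two, maps.q_vectors.reshape(-1, 3))
        ) ** 2
        np.testing.assert_allclose(pattern.ravel(), oracle, rtol=1e-9)

    def test_cross_term_averages_to_zero(self, small_detector):
        _, maps = small_detector
        a = cx.make_fixture("random_coil", n=20, seed=1)
        b = cx.make_fixture("random_coil", n=20, seed=2)
        rng = np.random.default_rng(4)
        qa, qb = random_quaternion(rng), random_quaternion(rng)
        # separation large enough that the fringe term oscillates many times
        # across the detector and its pixel average collapses
        da, db = np.array([200.0, 0, 0]), np.array([-200.0, 10.0, 0])
        both = multi_particle_pattern([(a, qa, da), (b, qb, db)], maps)
        only_a = multi_particle_pattern([(a, qa, da)], maps)
        only_b = multi_particle_pattern([(b, qb, db)], maps)
        cross = both - only_a - only_b
        # oscillating interference term: relative pixel average near zero
        assert abs(cross.mean()) < 0.02 * max(only_a.mean(), only_b.mean())

    def test_volume_in_coherent_sum_rejected(self, coil40, small_detector):
        _, maps = small_detector
        vol = build_volume(coil40, 0.4, n_grid=9)
        ident = np.array([1.0, 0, 0, 0])
        with pytest.raises(TypeError):
            multi_particle_pattern(
                [(vol, ident, np.zeros(3)), (coil40, ident, np.zeros(3))], maps
            )

    def test_empty_state_list_rejected(self, small_detector):
        _, maps = small_detector
        with pytest.raises(ValueError):
            multi_particle_pattern([], maps)


class TestPhotonQuantization:
    def test_zero_fluence_all_zero(self, coil40, small_detector):
        _, maps = small_detector
        pattern = np.ones(maps.shape)
        counts = pattern_to_photons(pattern, maps, fluence=0.0, seed=0)
        assert counts.sum() == 0

    def test_poisson_moments_at_lambda(self):
        lam = 3.2
        rng = np.random.default_rng(1)
        draws = rng.poisson(lam, size=100_000)
        se_mean = np.sqrt(lam / len(draws))
        # variance estimator SE for Poisson ~ sqrt((lam + 2 lam^2)/n)
        se_var = np.sqrt((lam + 2 * lam**2) / len(draws))
        assert draws.mean() == pytest.approx(lam, abs=3 * se_mean)
        assert draws.var() == pytest.approx(lam, abs=3 * se_var)

    def test_expected_counts_linear_in_fluence(self, small_detector):
        _, maps = small_detector
        pattern = np.full(maps.shape, 7.0)
        lam1 = expected_photons(pattern, maps, fluence=1e20)
        lam2 = expected_photons(pattern, maps, fluence=2e20)
        np.testing.assert_allclose(lam2, 2 * lam1, rtol=1e-12)

    def test_negative_pattern_rejected(self, small_detector):
        _, maps = small_detector
        with pytest.raises(ValueError):
            expected_photons(np.full(maps.shape, -1.0), maps, fluence=1.0)


class TestSolventBallProfile:
    def test_first_intensity_zero_at_qR(self):
        # continuum ball of radius R: first zero of the sphere form factor at
        # qR = 4.4934 (root of tan x = x)
        R = 15.0
        ball = cx.make_fixture("ball", radius=R, density=0.334, voxel=1.5)
        geom = cx.DetectorGeometry.monolithic(128, 100e-6, 0.04)
        maps = cx.pixel_maps(geom, 3.0)
        pattern = (
            np.abs(structure_factor_direct(ball, maps.q_vectors.reshape(-1, 3))) ** 2
        )
        q, prof = cx.radial_profile(pattern.reshape(maps.shape), maps, n_bins=120)
        valid = ~np.isnan(prof)
        q, prof = q[valid], prof[valid]
        sel = (q * R > 3.0) & (q * R < 5.5)
        q_zero = q[sel][np.argmin(prof[sel])]
        half_bin = (q[1] - q[0]) / 2
        assert abs(q_zero * R - 4.4934) <= half_bin * R
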