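import numpy as np
import pytest

import cxdisim as cx
from cxdisim.particle import element_form_factor_record

from conftest import write_toy_pdb


class TestFormFactors:
    @pytest.mark.parametrize(
        "element,electrons",
        [("H", 1), ("C", 6), ("N", 7), ("O", 8), ("P", 15), ("S", 16), ("Fe", 26), ("Au", 79)],
    )
    def test_forward_scattering_equals_electron_count(self, element, electrons):
        assert cx.form_factor(element, 0.0) == pytest.approx(electrons, abs=0.05)

    def test_nonincreasing_for_neutral_light_elements(self):
        q = np.linspace(0, 2 * 4 * np.pi, 200)  # s in 0..2 Å⁻¹
        for el in ("H", "C", "N", "O"):
            f = cx.form_factor(el, q)
            assert np.all(np.diff(f) <= 1e-12)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            cx.form_factor("Xx", 0.0)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            cx.form_factor("C", -1.0)

    def test_record_f0_property(self):
        rec = element_form_factor_record("C")
        assert rec.f0 == pytest.approx(6.0, abs=0.05)


class TestPdbReader:
    def test_single_atom_parse(self, tmp_path):
        path = write_toy_pdb(tmp_path / "one.pdb", [(0.0, 0.0, 0.0)], ["C"])
        p = cx.load_pdb(path)
        assert p.n_scatterers == 1
        assert p.species[0] == "C"
        np.testing.assert_allclose(p.positions, [[0, 0, 0]])

    def test_deterministic_reread(self, toy_pdb):
        path, _, _ = toy_pdb
        p1, p2 = cx.load_pdb(path), cx.load_pdb(path)
        np.testing.assert_array_equal(p1.positions, p2.positions)
        assert list(p1.species) == list(p2.species)

    def test_roundtrip_within_pdb_precision(self, tmp_path):
        rng = np.random.default_rng(4)
        positions = rng.uniform(-30, 30, size=(3, 3))
        path = write_toy_pdb(tmp_path / "rt.pdb", positions, ["C", "N", "O"])
        p = cx.load_pdb(path)
        np.testing.assert_allclose(p.positions, positions, atol=1e-3)

    def test_empty_after_filtering_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            cx.load_pdb(path)

    def test_unreadable_file_errors(self, tmp_path):
        with pytest.raises((ValueError, OSError)):
            cx.load_pdb(tmp_path / "nonexistent.pdb")


class TestH5ParticleIO:
    def test_constant_form_factor_records(self, tmp_path):
        import h5py

        path = tmp_path / "cg.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=np.zeros((10, 3)))
            g = f.create_group("form_factors")
            g.create_dataset("a", data=np.zeros((10, 4)))
            g.create_dataset("b", data=np.zeros((10, 4)))
            g.create_dataset("c", data=np.ones(10))
        p = cx.load_particle_h5(path)
        assert p.n_scatterers == 10
        f_vals = [p.registry[sp](0.7) for sp in p.species]
        np.testing.assert_allclose(f_vals, 1.0)

    def test_cross_reader_equality_with_pdb(self, toy_pdb, tmp_path):
        path, _, _ = toy_pdb
        from_pdb = cx.load_pdb(path)
        h5path = tmp_path / "same.h5"
        cx.save_particle_h5(h5path, from_pdb)
        from_h5 = cx.load_particle_h5(h5path)
        np.testing.assert_array_equal(from_pdb.positions, from_h5.positions)
        probe_q = np.linspace(0.0, 2.0, 10)
        for sp1, sp2 in zip(from_pdb.species, from_h5.species):
            np.testing.assert_array_equal(
                from_pdb.registry[sp1](probe_q), from_h5.registry[sp2](probe_q)
            )

    def test_mismatched_lengths_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=np.zeros((10, 3)))
            f.create_dataset("elements", data=np.array([b"C"] * 9))
        with pytest.raises(ValueError):
            cx.load_particle_h5(path)

    def test_missing_datasets_error(self, tmp_path):
        import h5py

        path = tmp_path / "none.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=np.zeros((5, 3)))
        with pytest.raises(ValueError):
            cx.load_particle_h5(path)


class TestHydrationLayer:
    def _single_atom(self):
        return cx.Particle(
            positions=np.zeros((1, 3)), species=np.array(["C"], dtype=object), registry={}
        )

    def test_shell_electron_total_matches_analytic_volume(self):
        probe, thickness, rho, voxel = 1.7, 6.0, 0.334, 0.5
        p = cx.add_hydration_layer(
            self._single_atom(), thickness, density=rho, voxel=voxel, probe_radius=probe
        )
        analytic = 4 / 3 * np.pi * ((probe + thickness) ** 3 - probe**3) * rho
        assert p.solvent_amplitudes.sum() == pytest.approx(analytic, rel=0.05)

    def test_density_linearity(self):
        p1 = cx.add_hydration_layer(self._single_atom(), 4.0, density=0.2, voxel=1.0)
        p2 = cx.add_hydration_layer(self._single_atom(), 4.0, density=0.4, voxel=1.0)
        np.testing.assert_allclose(p2.solvent_amplitudes, 2 * p1.solvent_amplitudes)

    def test_empty_shell_errors(self):
        # shell of width 3 Å around a point scatterer cannot hold any point of
        # a 3.1 Å lattice anchored on the particle
        with pytest.raises(ValueError):
            cx.add_hydration_layer(
                self._single_atom(), thickness=3.0, voxel=3.1, probe_radius=0.0
            )

    def test_shell_points_within_mask(self, coil40):
        thickness, probe = 4.0, 1.7
        p = cx.add_hydration_layer(coil40, thickness, voxel=1.5, probe_radius=probe)
        from scipy.spatial import cKDTree

        d = cKDTree(coil40.positions).query(p.solvent_points)[0]
        assert np.all(d > probe)
        assert np.all(d <= probe + thickness + 1e-9)

    def test_convergence_with_voxel_refinement(self):
        probe, thickness, rho = 1.7, 5.0, 0.334
        analytic = 4 / 3 * np.pi * ((probe + thickness) ** 3 - probe**3) * rho
        errs = []
        for voxel in (1.5, 0.75, 0.4):
            p = cx.add_hydration_layer(
                self._single_atom(), thickness, density=rho, voxel=voxel, probe_radius=probe
            )
            errs.append(abs(p.solvent_amplitudes.sum() - analytic) / analytic)
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.02


class TestCavityFill:
    def test_hollow_shell_interior_volume(self):
        shell = cx.make_fixture("shell", radius=15.0, thickness=4.0, spacing=1.5)
        rho, voxel, probe = 0.5, 1.0, 1.7
        filled = cx.fill_cavity(shell, density=rho, voxel=voxel, probe_radius=probe)
        added = filled.solvent_amplitudes.sum() - shell.solvent_amplitudes.sum()
        # independent Monte-Carlo oracle for the void volume: points inside the
        # inner shell surface and outside every probe sphere (spherical
        # symmetry identifies the interior without any flood fill)
        from scipy.spatial import cKDTree

        rng = np.random.default_rng(11)
        r_inner = 15.0 - 4.0 / 2
        box = 2 * r_inner
        pts = rng.uniform(-r_inner, r_inner, size=(200_000, 3))
        d = cKDTree(shell.positions).query(pts)[0]
        frac = np.mean((np.linalg.norm(pts, axis=1) < r_inner) & (d > probe))
        oracle = frac * box**3 * rho
        assert added == pytest.approx(oracle, rel=0.05)

    def test_solid_particle_warns_and_unchanged(self, coil40):
        solid = cx.make_fixture("two_atom", d=2.0)
        with pytest.warns(UserWarning):
            out = cx.fill_cavity(solid, density=0.3, voxel=1.0)
        np.testing.assert_array_equal(out.positions, solid.positions)
        assert len(out.solvent_points) == 0

    def test_zero_density_adds_zero_amplitude(self):
        shell = cx.make_fixture("shell", radius=12.0, thickness=4.0, spacing=1.5)
        filled = cx.fill_cavity(shell, density=0.0, voxel=1.5)
        added = filled.solvent_amplitudes[len(shell.solvent_amplitudes):]
        assert len(added) > 0
        assert np.all(added == 0.0)


class TestGoldReference:
    def test_count_matches_brute_force_enumeration(self):
        radius, a = 10.0, 4.08
        p = cx.gold_reference(radius, a)
        # independent enumeration of FCC sites
        n = int(np.ceil(radius / a)) + 1
        count = 0
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]) * a
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                for k in range(-n, n + 1):
                    for b in basis:
                        site = np.array([i, j, k]) * a + b
                        if np.linalg.norm(site) <= radius:
                            count += 1
        assert p.n_scatterers == count

    def test_all_sites_inside_sphere(self):
        p = cx.gold_reference(12.0)
        assert np.all(np.linalg.norm(p.positions, axis=1) <= 12.0 + 1e-9)
        assert set(p.species.tolist()) == {"Au"}

    def test_deterministic(self):
        p1 = cx.gold_reference(10.0)
        p2 = cx.gold_reference(10.0)
        np.testing.assert_array_equal(p1.positions, p2.positions)

    def test_too_small_radius_errors(self):
        with pytest.raises(ValueError):
            cx.gold_reference(1.0, 4.08)


class TestParticleInvariants:
    def test_at_least_one_scatterer(self):
        with pytest.raises(ValueError):
            cx.Particle(
                positions=np.empty((0, 3)),
                species=np.array([], dtype=object),
                registry={},
            )

    def test_nonfinite_positions_rejected(self):
        with pytest.raises(ValueError):
            cx.Particle(
                positions=np.array([[np.nan, 0, 0]]),
                species=np.array(["C"], dtype=object),
                registry={},
            )

    def test_negative_solvent_amplitude_rejected(self):
        with pytest.raises(ValueError):
            cx.Particle(
                positions=np.zeros((1, 3)),
                species=np.array(["C"], dtype=object),
                registry={},
                solvent_points=np.zeros((1, 3)),
                solvent_amplitudes=np.array([-1.0]),
            )
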