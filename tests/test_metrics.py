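import numpy as np
import pytest

from dyncon.metrics import (DensityMap, buried_surface_area, computed_bfactors,
                            duplex_rotation_angle, map_model_ccc, sasa,
                            simulate_density, sphere_points)
from dyncon.selections import Selection
from dyncon.structure import Ensemble

from conftest import make_structure


class TestSasa:
    def test_isolated_sphere_analytic(self):
        s = make_structure([[0, 0, 0]])
        area = sasa(s, n_points=960).total
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_distant_atoms_additive(self):
        s = make_structure([[0, 0, 0], [100, 0, 0]], resids=[1, 5])
        one = sasa(make_structure([[0, 0, 0]])).total
        assert sasa(s).total == pytest.approx(2 * one, rel=1e-9)

    def test_enclosed_atom_zero(self):
        shell = 3.0 * sphere_points(60)
        coords = np.vstack([[0.0, 0, 0], shell])
        resindex = [0] + [1] * 60
        s = make_structure(coords, atom_resindex=resindex, resids=[1, 5])
        rep = sasa(s)
        assert rep.atom_area[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_convergence(self):
        s = make_structure([[0, 0, 0]])
        exact = 4 * np.pi * 3.1 ** 2
        errs = [abs(sasa(s, n_points=n).total - exact) / exact
                for n in (240, 960, 3840)]
        assert all(e < 0.01 for e in errs)

    def test_hydrogens_ignored(self):
        s = make_structure([[0, 0, 0], [1.0, 0, 0]], names=["CA", "HA"],
                           elements=["C", "H"], atom_resindex=[0, 0])
        lone = make_structure([[0, 0, 0]])
        assert sasa(s).total == pytest.approx(sasa(lone).total)

    def test_unknown_element_warns(self):
        s = make_structure([[0, 0, 0]], elements=["XX"])
        with pytest.warns(UserWarning, match="unknown element"):
            sasa(s)

    def test_matches_biotite_on_random_cluster(self):
        """Independent cross-check against biotite's Shrake–Rupley."""
        import biotite.structure as struc

        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 8, (10, 3))
        s = make_structure(coords)
        mine = sasa(s, n_points=960)
        arr = struc.AtomArray(10)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 10)
        arr.res_id = np.arange(10) + 1
        arr.atom_name = np.array(["CA"] * 10)
        arr.res_name = np.array(["ALA"] * 10)
        arr.chain_id = np.array(["A"] * 10)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii="Single")
        # different radius tables/point meshes: agree within a few percent
        assert mine.total == pytest.approx(float(ref.sum()), rel=0.05)


class TestBsa:
    def test_noninteracting_groups_zero(self):
        s = make_structure([[0, 0, 0], [100, 0, 0]], resids=[1, 5])
        rep = buried_surface_area(s, {0}, {1})
        assert abs(rep["bsa"]) < 1.0

    def test_two_sphere_analytic_cap(self):
        # expanded radius R = 3.1 Å, centres 4.0 Å apart
        s = make_structure([[0, 0, 0], [4.0, 0, 0]], resids=[1, 5])
        rep = buried_surface_area(s, {0}, {1}, n_points=3840)
        exact = 2 * 2 * np.pi * 3.1 * (3.1 - 2.0)
        assert abs(rep["bsa"] - exact) / exact < 0.02

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(1)
        s = make_structure(rng.uniform(0, 10, (8, 3)),
                           resids=1 + 2 * np.arange(8))
        a, b = set(range(4)), set(range(4, 8))
        assert buried_surface_area(s, a, b)["bsa"] == pytest.approx(
            buried_surface_area(s, b, a)["bsa"])

    def test_subgroup_equal_to_group_gives_total(self):
        s = make_structure([[0, 0, 0], [4.0, 0, 0]], resids=[1, 5])
        rep = buried_surface_area(s, {0}, {1}, subgroups={"all_a": {0}})
        assert rep["subgroups"]["all_a"]["bsa"] == pytest.approx(rep["bsa"])
        assert rep["subgroups"]["all_a"]["percent"] == pytest.approx(100.0)

    def test_halved_flag(self):
        s = make_structure([[0, 0, 0], [4.0, 0, 0]], resids=[1, 5])
        full = buried_surface_area(s, {0}, {1})["bsa"]
        half = buried_surface_area(s, {0}, {1}, halved=True)["bsa"]
        assert half == pytest.approx(full / 2)

    def test_overlapping_groups_rejected(self):
        s = make_structure([[0, 0, 0], [4.0, 0, 0]], resids=[1, 5])
        with pytest.raises(ValueError):
            buried_surface_area(s, {0, 1}, {1})


class TestBfactors:
    def _gauss_ensemble(self, sigma, T=10_000, seed=0):
        rng = np.random.default_rng(seed)
        top = make_structure([[0, 0, 0], [60, 0, 0], [0, 60, 0]],
                             resids=[1, 5, 9])
        frames = top.coords[None] + rng.normal(0, sigma, (T, 3, 3))
        return Ensemble(topology=top, frames=frames)

    def test_zero_fluctuation_zero_b(self):
        ens = self._gauss_ensemble(0.0, T=5)
        assert np.allclose(computed_bfactors(ens, superpose_iterations=0), 0.0)

    def test_gaussian_analytic_value(self):
        ens = self._gauss_ensemble(0.5)
        b = computed_bfactors(ens, superpose_iterations=0)
        expect = 8 * np.pi ** 2 * 0.25
        assert np.all(np.abs(b - expect) / expect < 0.05)

    def test_doubling_sigma_quadruples_b(self):
        b1 = computed_bfactors(self._gauss_ensemble(0.4, T=20_000, seed=1),
                               superpose_iterations=0)
        b2 = computed_bfactors(self._gauss_ensemble(0.8, T=20_000, seed=1),
                               superpose_iterations=0)
        assert np.allclose(b2 / b1, 4.0, rtol=0.05)

    def test_single_frame_rejected(self):
        top = make_structure([[0, 0, 0]])
        ens = Ensemble(topology=top, frames=top.coords[None])
        with pytest.raises(ValueError):
            computed_bfactors(ens)


def _rotation_fixture(theta_deg):
    rng = np.random.default_rng(7)
    anchor = rng.uniform(-10, 10, (6, 3))
    duplex = rng.uniform(-5, 5, (6, 3)) + np.array([30.0, 0, 0])
    th = np.radians(theta_deg)
    Rz = np.array([[np.cos(th), -np.sin(th), 0],
                   [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    center = duplex.mean(axis=0)
    rotated = (duplex - center) @ Rz.T + center
    chains = ["A"] * 6 + ["B"] * 6
    resids = list(range(1, 13))
    a = make_structure(np.vstack([anchor, duplex]), chains=chains,
                       resids=resids)
    b = make_structure(np.vstack([anchor, rotated]), chains=chains,
                       resids=resids)
    return a, b


class TestDuplexRotation:
    def test_identical_frames_zero(self):
        a, _ = _rotation_fixture(14.0)
        angle, _ = duplex_rotation_angle(a, a, Selection("chain A"),
                                         Selection("chain B"))
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_constructed_fourteen_degrees(self):
        a, b = _rotation_fixture(14.0)
        angle, axis = duplex_rotation_angle(a, b, Selection("chain A"),
                                            Selection("chain B"))
        assert angle == pytest.approx(14.0, abs=1e-6)
        assert abs(axis[2]) == pytest.approx(1.0, abs=1e-6)

    def test_forward_then_back_composes_to_zero(self):
        a, b = _rotation_fixture(9.0)
        fwd, _ = duplex_rotation_angle(a, b, Selection("chain A"),
                                       Selection("chain B"))
        rev, _ = duplex_rotation_angle(b, a, Selection("chain A"),
                                       Selection("chain B"))
        assert fwd == pytest.approx(rev, abs=1e-9)  # undirected magnitude

    def test_collinear_selection_rejected(self):
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0], [11, 0, 0],
                  [12, 0, 0]]
        chains = ["A"] * 3 + ["B"] * 3
        s = make_structure(coords, chains=chains, resids=range(1, 7))
        with pytest.raises(ValueError, match="non-collinear"):
            duplex_rotation_angle(s, s, Selection("chain A"),
                                  Selection("chain B"))


class TestCcc:
    def _model(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        return make_structure(rng.uniform(8, 24, (n, 3)),
                              resids=1 + 2 * np.arange(n))

    def test_self_correlation_unity(self):
        s = self._model()
        sim = simulate_density(s, (32, 32, 32), 1.0, np.zeros(3), 4.0)
        assert map_model_ccc(s, sim, 4.0) == pytest.approx(1.0, abs=1e-6)

    def test_noise_map_uncorrelated(self):
        rng = np.random.default_rng(3)
        s = self._model()
        noise = DensityMap(rng.normal(0, 1, (48, 48, 48)), 1.0,
                           np.array([-8.0, -8.0, -8.0]))
        assert abs(map_model_ccc(s, noise, 4.0)) < 0.05

    def test_translated_model_correlates_worse(self):
        s = self._model()
        sim = simulate_density(s, (64, 64, 64), 1.0, np.zeros(3), 4.0)
        shifted = make_structure(s.coords + np.array([20.0, 0, 0]),
                                 resids=s.resseq)
        in_place = map_model_ccc(s, sim, 4.0)
        moved = map_model_ccc(shifted, sim, 4.0)
        assert moved < in_place

    def test_invariant_under_affine_rescaling(self):
        s = self._model(seed=5)
        sim = simulate_density(s, (32, 32, 32), 1.0, np.zeros(3), 4.0)
        scaled = DensityMap(3.7 * sim.data + 11.0, 1.0, np.zeros(3))
        assert map_model_ccc(s, scaled, 4.0) == pytest.approx(
            map_model_ccc(s, sim, 4.0), abs=1e-9)

    def test_model_outside_map_rejected(self):
        s = self._model()
        tiny = DensityMap(np.zeros((4, 4, 4)), 1.0, np.zeros(3))
        with pytest.raises(ValueError, match="outside"):
            map_model_ccc(s, tiny, 4.0)

    def test_ccp4_round_trip(self, tmp_path):
        import gemmi

        from dyncon.metrics import read_ccp4_map

        s = self._model(seed=9)
        sim = simulate_density(s, (24, 24, 24), 1.5, np.zeros(3), 5.0)
        grid = gemmi.FloatGrid(*sim.data.shape)
        grid.set_unit_cell(gemmi.UnitCell(24 * 1.5, 24 * 1.5, 24 * 1.5,
                                          90, 90, 90))
        arr = np.array(grid, copy=False)
        arr[...] = sim.data
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        path = str(tmp_path / "d.ccp4")
        m.write_ccp4_map(path)
        back = read_ccp4_map(path, resolution=5.0)
        assert back.voxel == pytest.approx(1.5)
        assert np.allclose(back.data, sim.data, atol=1e-4)
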