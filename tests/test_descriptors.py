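"""Geometry-level descriptor tests: dipoles, inertia axes, projection areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porinperm import (
    ConformerEnsemble,
    DescriptorSettings,
    dipole_vector,
    ensemble_descriptors,
    main_inertia_axis,
    make_toy_molecule,
    minimal_projection_area,
    net_charge,
    projection_area,
    transversal_dipole,
)
from porinperm.descriptors import (
    EA_TO_DEBYE,
    fibonacci_hemisphere,
    projection_area_monte_carlo,
)

Z = np.array([0.0, 0.0, 1.0])


def single_conformer(positions, charges, radii=None, masses=None, cid="x"):
    n = len(charges)
    return ConformerEnsemble(
        compound_id=cid,
        positions=np.asarray(positions)[None, :, :],
        charges=np.asarray(charges, dtype=float),
        radii=np.full(n, 1.5) if radii is None else np.asarray(radii),
        masses=np.full(n, 12.0) if masses is None else np.asarray(masses),
    )


class TestNetCharge:
    @pytest.mark.parametrize(
        "charges, expected",
        [
            ([0.5, 0.499], 1),  # near-integer sum rounds
            ([1.0, -1.0], 0),  # zwitterion is net neutral
            ([0.0, 0.0, 0.0], 0),
        ],
    )
    def test_rounds_partial_charge_sum(self, charges, expected):
        positions = np.arange(3 * len(charges), dtype=float).reshape(-1, 3)
        ens = single_conformer(positions, charges)
        assert net_charge(ens) == expected

    def test_non_integral_sum_rejected_with_residual(self):
        positions = np.arange(6, dtype=float).reshape(2, 3)
        with pytest.raises(ValueError, match="0.5"):
            single_conformer(positions, [0.25, 0.25])


class TestDipole:
    def test_diatomic_closed_form(self):
        ens = make_toy_molecule("diatomic", {"q": 0.5, "d": 2.0})
        mu = dipole_vector(ens.positions[0], ens.charges, ens.masses)
        assert np.linalg.norm(mu) == pytest.approx(EA_TO_DEBYE, rel=1e-12)

    def test_zero_charges_zero_dipole(self):
        ens = make_toy_molecule("rod")
        mu = dipole_vector(ens.positions[0], ens.charges, ens.masses)
        assert np.linalg.norm(mu) == 0.0

    def test_net_charged_species_uses_center_of_mass(self):
        # (+1, 0) at (+-1, 0, 0), equal masses: COM at origin, |mu| = 1 e*A
        positions = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        mu = dipole_vector(positions, [1.0, 0.0], masses=[10.0, 10.0])
        assert np.linalg.norm(mu) == pytest.approx(EA_TO_DEBYE, rel=1e-12)

    def test_empty_atom_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dipole_vector(np.empty((0, 3)), np.empty(0))


class TestInertiaAxis:
    def test_linear_molecule_long_axis(self):
        positions = np.array([[0, 0, -1.0], [0, 0, 0.0], [0, 0, 1.0]])
        axis = main_inertia_axis(positions, np.ones(3))
        assert np.allclose(axis, Z)

    def test_matches_bruteforce_eigendecomposition(self):
        rng = np.random.default_rng(7)
        positions = rng.normal(size=(10, 3))
        masses = rng.uniform(1, 16, size=10)
        axis = main_inertia_axis(positions, masses)
        # independent oracle: explicit double-loop tensor assembly
        com = (masses[:, None] * positions).sum(0) / masses.sum()
        centered = positions - com
        tensor = np.zeros((3, 3))
        for m, r in zip(masses, centered):
            tensor += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
        vals, vecs = np.linalg.eigh(tensor)
        expected = vecs[:, 0]
        assert abs(abs(axis @ expected) - 1.0) < 1e-9

    def test_planar_ring_degenerate_pair_is_deterministic(self):
        ens = make_toy_molecule("ring")
        a1 = main_inertia_axis(ens.positions[0], ens.masses)
        a2 = main_inertia_axis(ens.positions[0], ens.masses)
        assert np.allclose(a1, a2)
        # in-plane axis: perpendicular to the ring normal
        assert abs(a1 @ Z) < 1e-8
        assert np.linalg.norm(a1) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_atoms_rejected(self):
        positions = np.zeros((3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            main_inertia_axis(positions, np.ones(3))


class TestTransversalDipole:
    def test_parallel_perpendicular_and_pythagorean_case(self):
        assert transversal_dipole(np.array([0, 0, 5.0]), Z) == pytest.approx(0.0, abs=1e-12)
        assert transversal_dipole(np.array([5.0, 0, 0]), Z) == pytest.approx(5.0)
        mu = np.array([3.0, 4.0, 0.0])
        assert transversal_dipole(mu, np.array([1.0, 0, 0])) == pytest.approx(4.0)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            transversal_dipole(np.ones(3), np.array([1.0, 1.0, 0.0]))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    def test_pythagorean_identity(self, mu, axis):
        mu = np.array(mu)
        axis = np.array(axis)
        norm = np.linalg.norm(axis)
        if norm < 1e-3:
            return
        axis = axis / norm
        perp = transversal_dipole(mu, axis)
        parallel = mu @ axis
        assert perp**2 + parallel**2 == pytest.approx(
            float(mu @ mu), abs=1e-9 * max(1.0, float(mu @ mu))
        )


class TestProjectionArea:
    def test_single_atom_closed_form(self):
        area = projection_area(np.zeros((1, 3)), [1.7], Z, resolution=0.05)
        assert area == pytest.approx(np.pi * 1.7**2, rel=0.01)

    def test_union_idempotence_for_superposed_atoms(self):
        one = projection_area(np.zeros((1, 3)), [1.5], Z, resolution=0.1)
        two = projection_area(np.zeros((2, 3)), [1.5, 1.5], Z, resolution=0.1)
        assert two == one

    def test_disjoint_atoms_add_and_match_monte_carlo(self):
        positions = np.array([[0, 0, 0], [10.0, 0, 0]])
        radii = np.array([1.5, 1.5])
        # fine raster: small isolated disks carry the largest relative
        # lattice fluctuation, so probe them at 0.05 A
        grid = projection_area(positions, radii, Z, resolution=0.05)
        assert grid == pytest.approx(2 * np.pi * 1.5**2, rel=0.01)
        mc = projection_area_monte_carlo(positions, radii, Z, 10**6, seed=3)
        assert abs(grid - mc) / mc < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            projection_area(np.zeros((1, 3)), [1.5], Z, resolution=0.0)
        with pytest.raises(ValueError, match="unit"):
            projection_area(np.zeros((1, 3)), [1.5], np.array([0, 0, 2.0]))

    def test_rotation_invariance_with_corotated_direction(self):
        from scipy.spatial.transform import Rotation

        ens = make_toy_molecule("random_cloud", {"n_atoms": 8}, seed=11)
        pos, radii = ens.positions[0], ens.radii
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        d = np.array([0.3, -0.5, 0.81])
        d /= np.linalg.norm(d)
        a0 = projection_area(pos, radii, d, 0.1)
        a1 = projection_area(pos @ rot.T, radii, rot @ d, 0.1)
        assert abs(a1 - a0) / a0 < 0.02

    def test_monotone_under_adding_atom(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-3, 3, size=(7, 3))
        radii = rng.uniform(1.2, 1.8, size=7)
        sub = projection_area(pos[:-1], radii[:-1], Z, 0.1)
        full = projection_area(pos, radii, Z, 0.1)
        assert full >= sub


class TestMinimalProjectionArea:
    def test_sphere_isotropic(self):
        mpa, _ = minimal_projection_area(
            np.zeros((1, 3)), [1.5], n_directions=16, resolution=0.05
        )
        assert mpa == pytest.approx(np.pi * 1.5**2, rel=0.01)

    def test_rod_viewed_down_axis(self):
        ens = make_toy_molecule("rod", {"n_atoms": 5, "radius": 1.5})
        mpa, direction = minimal_projection_area(
            ens.positions[0], ens.radii, n_directions=128, resolution=0.1
        )
        assert mpa == pytest.approx(np.pi * 1.5**2, rel=0.02)
        assert abs(direction @ Z) > 0.99  # looks down the rod

    def test_never_exceeds_probed_directions(self):
        ens = make_toy_molecule("random_cloud", {"n_atoms": 6}, seed=4)
        pos, radii = ens.positions[0], ens.radii
        mpa, _ = minimal_projection_area(pos, radii, 64, 0.15)
        for d in fibonacci_hemisphere(64)[::8]:
            assert mpa <= projection_area(pos, radii, d, 0.15) + 1e-12

    def test_close_to_dense_direction_scan(self):
        for seed in (0, 1):
            ens = make_toy_molecule("random_cloud", {"n_atoms": 7}, seed=seed)
            pos, radii = ens.positions[0], ens.radii
            mpa, _ = minimal_projection_area(pos, radii, 256, 0.3)
            brute = min(
                projection_area(pos, radii, d, 0.3)
                for d in fibonacci_hemisphere(2000)
            )
            assert abs(mpa - brute) / brute < 0.02

    def test_mpa_monotone_under_adding_atom(self):
        # identical direction sets (refine off) make monotonicity exact
        rng = np.random.default_rng(8)
        pos = rng.uniform(-2.5, 2.5, size=(6, 3))
        radii = rng.uniform(1.2, 1.8, size=6)
        sub, _ = minimal_projection_area(pos[:-1], radii[:-1], 64, 0.15, refine=False)
        full, _ = minimal_projection_area(pos, radii, 64, 0.15, refine=False)
        assert full >= sub


class TestEnsembleDescriptors:
    settings_fast = DescriptorSettings(n_directions=64, grid_resolution=0.2)

    def test_single_conformer_sd_zero(self):
        ens = make_toy_molecule("random_cloud", {"n_atoms": 6}, seed=1)
        d = ensemble_descriptors(ens, alogp=1.2, settings=self.settings_fast)
        assert d.mpa_sd == 0.0
        assert d.alogp == 1.2
        assert d.total_dipole_mean >= d.transversal_dipole_mean >= 0

    def test_replicated_conformers_match_single(self):
        ens1 = make_toy_molecule("random_cloud", {"n_atoms": 6}, seed=2)
        ens3 = ConformerEnsemble(
            compound_id=ens1.compound_id,
            positions=np.repeat(ens1.positions, 3, axis=0),
            charges=ens1.charges,
            radii=ens1.radii,
            masses=ens1.masses,
        )
        d1 = ensemble_descriptors(ens1, 0.0, self.settings_fast)
        d3 = ensemble_descriptors(ens3, 0.0, self.settings_fast)
        assert d3.mpa_mean == pytest.approx(d1.mpa_mean, rel=1e-12)
        assert d3.mpa_sd == pytest.approx(0.0, abs=1e-9)
        assert d3.total_dipole_mean == pytest.approx(d1.total_dipole_mean)

    def test_mean_and_sd_match_per_conformer_arithmetic(self):
        ens = make_toy_molecule(
            "random_cloud", {"n_atoms": 6, "n_conformers": 3}, seed=3
        )
        d = ensemble_descriptors(ens, 0.0, self.settings_fast)
        mpas = [
            minimal_projection_area(
                conf, ens.radii, n_directions=64, resolution=0.2
            )[0]
            for conf in ens.positions
        ]
        assert d.mpa_mean == pytest.approx(np.mean(mpas), rel=1e-12)
        assert d.mpa_sd == pytest.approx(np.std(mpas), rel=1e-9)
        assert min(mpas) <= d.mpa_mean <= max(mpas)
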