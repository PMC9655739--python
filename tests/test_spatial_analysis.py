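"""Cylindrical profiles, RDFs, gyration, superposition, RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nanobrush import spatial_analysis as spa
from nanobrush.core import EmptyInputError, MolecularSystem, Trajectory
from nanobrush.synthetic_ensemble import ideal_gas_frames


def _point_trajectory(coords, box=10.0, n_frames=1, masses=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    top = MolecularSystem(
        names=np.array([f"X{i}" for i in range(n)], dtype=object),
        elements=np.full(n, "C", dtype=object),
        groups=np.full(n, "PEPTIDE", dtype=object),
        resids=np.arange(n), resnames=np.full(n, "PT", dtype=object),
        positions=coords, charges=np.zeros(n), sigmas=np.zeros(n),
        epsilons=np.zeros(n),
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        box=box)
    frames = np.tile(coords, (n_frames, 1, 1))
    return Trajectory(topology=top, frames=frames,
                      times=np.arange(n_frames, dtype=float))


class TestCylindricalDensity:
    def test_single_atom_lands_in_its_shell(self):
        traj = _point_trajectory([[0.55, 0.0, 0.0]])
        prof = spa.cylindrical_density(traj, [0], bin_width=0.1,
                                       shell_length=4.1, r_max=1.0)
        assert prof.counts[5] == 1.0
        assert prof.counts.sum() == 1.0
        assert prof.values[5] == pytest.approx(
            1.0 / (np.pi * (0.6 ** 2 - 0.5 ** 2) * 4.1))

    def test_count_conservation(self):
        traj = ideal_gas_frames(4.0, 300, 20, seed=3)
        prof = spa.cylindrical_density(traj, np.arange(300), bin_width=0.1,
                                       shell_length=3.0)
        in_slab = (np.abs(traj.frames[..., 2]) <= 1.5).sum(axis=1).mean()
        assert prof.counts.sum() == pytest.approx(in_slab)

    def test_empty_inputs(self):
        traj = _point_trajectory([[0.1, 0.0, 0.0]])
        with pytest.raises(EmptyInputError):
            spa.cylindrical_density(traj, [])


class TestRDF:
    def test_fixed_pair_single_bin(self):
        traj = _point_trajectory([[0.0, 0.0, 0.0], [0.32, 0.0, 0.0]], box=4.0)
        res = spa.rdf(traj, [0], [1], dr=0.02, r_max=1.0)
        nonzero = np.flatnonzero(res.pair_counts)
        assert len(nonzero) == 1
        assert res.bin_centers[nonzero[0]] == pytest.approx(0.33, abs=0.011)

    def test_range_error(self):
        traj = _point_trajectory([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], box=4.0)
        with pytest.raises(ValueError):
            spa.rdf(traj, [0], [1], r_max=3.0)

    def test_self_rdf_single_atom(self):
        traj = _point_trajectory([[0.0, 0.0, 0.0]])
        with pytest.raises(EmptyInputError):
            spa.rdf(traj, [0], [0])


class TestComSidewall:
    def test_arithmetic(self):
        traj = _point_trajectory([[1.1915, 0.0, 0.0]])
        d, mean, sd = spa.com_sidewall_distance(traj, [0], 0.3915)
        assert mean == pytest.approx(0.8)
        assert sd == 0.0

    def test_on_wall_and_signed(self):
        traj = _point_trajectory([[0.3915, 0.0, 0.0]])
        _, mean, _ = spa.com_sidewall_distance(traj, [0], 0.3915)
        assert mean == pytest.approx(0.0, abs=1e-12)
        traj2 = _point_trajectory([[0.2, 0.0, 0.0]])
        _, mean2, _ = spa.com_sidewall_distance(traj2, [0], 0.3915)
        assert mean2 < 0  # penetration reported, not clipped

    def test_zero_mass(self):
        traj = _point_trajectory([[1.0, 0.0, 0.0]], masses=[0.0])
        with pytest.raises(EmptyInputError):
            spa.com_sidewall_distance(traj, [0], 0.39)


class TestGyration:
    def test_two_unit_masses(self):
        rg, rx, ry, rz = spa.gyration(np.array([[0.5, 0, 0], [-0.5, 0, 0]]))
        assert (rg, rx, ry, rz) == (0.5, 0.5, 0.0, 0.0)

    def test_brute_force_oracle(self, rng):
        coords = rng.normal(size=(100, 3))
        masses = rng.uniform(1.0, 16.0, 100)
        rg, rx, ry, rz = spa.gyration(coords, masses)
        com = np.zeros(3)
        mtot = masses.sum()
        for m, r in zip(masses, coords):
            com += m * r / mtot
        acc = np.zeros(3)
        for m, r in zip(masses, coords):       # explicit double-sum-free oracle
            acc += m * (r - com) ** 2 / mtot
        assert rg ** 2 == pytest.approx(acc.sum(), abs=1e-12)
        assert (rx ** 2, ry ** 2, rz ** 2) == pytest.approx(tuple(acc), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 10, 20)
        rot = Rotation.random(random_state=np.random.RandomState(seed % 2 ** 16))
        rg1, *comp1 = spa.gyration(coords, masses)
        rg2, *comp2 = spa.gyration(coords @ rot.as_matrix().T, masses)
        assert rg1 == pytest.approx(rg2, abs=1e-10)      # Rg invariant
        # component identity holds in both orientations
        assert sum(c ** 2 for c in comp1) == pytest.approx(rg1 ** 2, abs=1e-12)
        assert sum(c ** 2 for c in comp2) == pytest.approx(rg2 ** 2, abs=1e-12)


class TestSuperpose:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        rot, trans, rmsd = spa.superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_known_transform(self, rng):
        coords = rng.normal(size=(15, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ R.T + np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = spa.superpose(moved, coords)
        assert rmsd <= 1e-10
        assert np.allclose(rot @ R, np.eye(3), atol=1e-8)

    def test_rotation_is_proper_even_for_mirror(self, rng):
        coords = rng.normal(size=(25, 3))
        mirror = coords * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = spa.superpose(mirror, coords)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1  # reflections rejected, not absorbed

    def test_degenerate_inputs(self):
        with pytest.raises(spa.DegenerateSuperpositionError):
            spa.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(spa.DegenerateSuperpositionError):
            spa.superpose(line, line)

    def test_noisy_copy_matches_numeric_minimizer(self, rng):
        """Kabsch result equals an independent numeric optimisation over
        rotation vectors on a jittered copy."""
        coords = rng.normal(size=(50, 3))
        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        noisy = (coords + rng.normal(0, 0.01, coords.shape)) @ R.T + [0.3, 0, 0]
        _, _, rmsd = spa.superpose(noisy, coords)

        def objective(rv):
            rot = Rotation.from_rotvec(rv).as_matrix()
            a = noisy @ rot.T
            a = a - a.mean(0) + coords.mean(0)
            return np.sqrt(((a - coords) ** 2).sum(1).mean())

        best = min(minimize(objective, x0, method="Nelder-Mead").fun
                   for x0 in (np.zeros(3), [0.5, 0.5, 0.5], [-1, 0, 1]))
        assert rmsd <= best + 1e-6
        assert rmsd == pytest.approx(best, rel=1e-3)


class TestRMSDSeries:
    def test_repeated_frame_all_zero(self):
        traj = ideal_gas_frames(4.0, 30, 1, seed=0)
        frames = np.tile(traj.frames[0], (5, 1, 1))
        rep = Trajectory(topology=traj.topology, frames=frames,
                         times=np.arange(5.0))
        series = spa.rmsd_series(rep, np.arange(30))
        assert np.allclose(series.rmsd, 0.0, atol=1e-12)

    def test_translation_without_superposition(self):
        base = ideal_gas_frames(4.0, 30, 1, seed=1).frames[0]
        shift = np.array([0.3, -0.4, 1.2])
        frames = np.stack([base, base + shift])
        traj = Trajectory(topology=ideal_gas_frames(4.0, 30, 1, seed=1).topology,
                          frames=frames, times=np.array([0.0, 10.0]))
        series = spa.rmsd_series(traj, np.arange(30), superpose_frames=False)
        assert series.rmsd[0] == 0.0
        assert series.rmsd[1] == pytest.approx(np.linalg.norm(shift))

    def test_rotation_with_superposition(self):
        base = ideal_gas_frames(4.0, 30, 1, seed=2).frames[0]
        R = Rotation.from_euler("y", 71, degrees=True).as_matrix()
        frames = np.stack([base, base @ R.T])
        traj = Trajectory(topology=ideal_gas_frames(4.0, 30, 1, seed=2).topology,
                          frames=frames, times=np.array([0.0, 10.0]))
        series = spa.rmsd_series(traj, np.arange(30), superpose_frames=True)
        assert np.all(series.rmsd <= 1e-10)

    def test_missing_reference(self):
        traj = ideal_gas_frames(4.0, 10, 2, seed=0)
        with pytest.raises(EmptyInputError):
            spa.rmsd_series(traj, np.arange(10), reference=5)
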