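"""Pair energies, Poisson-Boltzmann solvation, SASA, MM-PBSA assembly."""

import numpy as np
import pytest

from nanobrush import energetics as E
from nanobrush.core import F_COULOMB, MolecularSystem, Trajectory

BORN_EXACT = -0.5 * F_COULOMB * (1.0 - 1.0 / 78.4) / 0.2


class TestLennardJones:
    def test_zero_at_sigma(self):
        e = E.lj_energy(np.zeros((1, 3)), [0.3], [0.5],
                        np.array([[0.3, 0, 0]]), [0.3], [0.5])
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth(self):
        r = 2.0 ** (1.0 / 6.0) * 0.3
        e = E.lj_energy(np.zeros((1, 3)), [0.3], [0.5],
                        np.array([[r, 0, 0]]), [0.3], [0.5])
        assert e == pytest.approx(-0.5, rel=1e-12)

    def test_bruteforce_oracle(self, rng):
        pa = rng.uniform(0, 2, (50, 3))
        pb = rng.uniform(3, 5, (50, 3))
        sa, sb = rng.uniform(0.2, 0.4, 50), rng.uniform(0.2, 0.4, 50)
        ea, eb = rng.uniform(0.1, 1.0, 50), rng.uniform(0.1, 1.0, 50)
        fast = E.lj_energy(pa, sa, ea, pb, sb, eb)
        slow = 0.0
        for i in range(50):
            for j in range(50):
                r = np.linalg.norm(pa[i] - pb[j])
                s = np.sqrt(sa[i] * sb[j])
                ep = np.sqrt(ea[i] * eb[j])
                slow += 4 * ep * ((s / r) ** 12 - (s / r) ** 6)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_singularity(self):
        with pytest.raises(E.SingularityError):
            E.lj_energy(np.zeros((1, 3)), [0.3], [0.5],
                        np.zeros((1, 3)), [0.3], [0.5])


class TestCoulomb:
    def test_unit_charges_at_one_nm(self):
        e = E.coulomb_energy(np.zeros((1, 3)), [1.0],
                             np.array([[1.0, 0, 0]]), [1.0])
        assert e == pytest.approx(138.935458, abs=1e-9)

    def test_zero_charge(self):
        e = E.coulomb_energy(np.zeros((1, 3)), [0.0],
                             np.array([[1.0, 0, 0]]), [1.0])
        assert e == 0.0

    def test_bruteforce_oracle(self, rng):
        pa = rng.uniform(0, 2, (30, 3))
        pb = rng.uniform(3, 5, (30, 3))
        qa, qb = rng.uniform(-1, 1, 30), rng.uniform(-1, 1, 30)
        fast = E.coulomb_energy(pa, qa, pb, qb)
        slow = sum(F_COULOMB * qa[i] * qb[j] / np.linalg.norm(pa[i] - pb[j])
                   for i in range(30) for j in range(30))
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_translation_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        pa = rng.uniform(0, 1, (10, 3))
        pb = rng.uniform(2, 3, (10, 3))
        qa, qb = rng.uniform(-1, 1, 10), rng.uniform(-1, 1, 10)
        e1 = E.coulomb_energy(pa, qa, pb, qb)
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        t = np.array([5.0, -3.0, 1.0])
        e2 = E.coulomb_energy(pa @ R.T + t, qa, pb @ R.T + t, qb)
        assert e1 == pytest.approx(e2, rel=1e-10)


class TestPoissonBoltzmann:
    def test_born_ion_within_3_percent(self):
        g = E.solve_pb(np.zeros((1, 3)), [1.0], [0.2],
                       E.PBConfig(grid_spacing=0.05, eps_in=1.0))
        assert abs(g / BORN_EXACT - 1.0) < 0.03

    def test_zero_charges(self):
        assert E.solve_pb(np.zeros((2, 3)) + [[0, 0, 0], [0.5, 0, 0]],
                          [0.0, 0.0], [0.2, 0.2]) == 0.0

    def test_equal_dielectrics_vanish(self):
        g = E.solve_pb(np.zeros((1, 3)), [1.0], [0.2],
                       E.PBConfig(grid_spacing=0.1, eps_in=78.4, eps_out=78.4))
        assert abs(g) < 1e-6

    def test_sign_negative_for_charged_solute(self):
        g = E.solve_pb(np.array([[0.0, 0, 0], [0.3, 0, 0]]), [0.6, 0.4],
                       [0.18, 0.22], E.PBConfig(grid_spacing=0.1))
        assert g < 0

    def test_polarity_grows_with_eps_out(self):
        lo = E.solve_pb(np.zeros((1, 3)), [1.0], [0.2],
                        E.PBConfig(grid_spacing=0.1, eps_in=1.0, eps_out=20.0))
        hi = E.solve_pb(np.zeros((1, 3)), [1.0], [0.2],
                        E.PBConfig(grid_spacing=0.1, eps_in=1.0, eps_out=78.4))
        assert abs(hi) > abs(lo)

    def test_salt_screens_boundary_potential(self):
        # with kappa > 0 the screened Debye-Hueckel boundary potential is
        # everywhere smaller in magnitude than the salt-free one
        g0 = E.solve_pb(np.zeros((1, 3)), [1.0], [0.2],
                        E.PBConfig(grid_spacing=0.1, eps_in=1.0))
        gs = E.solve_pb(np.zeros((1, 3)), [1.0], [0.2],
                        E.PBConfig(grid_spacing=0.1, eps_in=1.0,
                                   ionic_strength=0.154))
        assert gs < g0 < 0  # screening stabilises the ion further


class TestSASA:
    def test_single_sphere_closed_form(self):
        _, total = E.sasa(np.zeros((1, 3)), [0.2])
        assert abs(total / (4 * np.pi * 0.34 ** 2) - 1.0) < 0.01

    def test_far_spheres_additive(self):
        _, one = E.sasa(np.zeros((1, 3)), [0.2])
        _, two = E.sasa(np.array([[0, 0, 0], [5.0, 0, 0]]), [0.2, 0.2])
        assert two == pytest.approx(2 * one, rel=1e-2)

    def test_buried_sphere_is_zero(self):
        areas, _ = E.sasa(np.array([[0, 0, 0], [0.01, 0, 0]]), [0.3, 0.05])
        assert areas[1] == 0.0

    def test_monotone_burial(self, rng):
        """Adding an atom never increases any existing atom's exposure."""
        pos = rng.uniform(0, 1.0, (12, 3))
        rad = rng.uniform(0.1, 0.2, 12)
        before, _ = E.sasa(pos, rad)
        pos2 = np.vstack([pos, rng.uniform(0, 1.0, 3)])
        rad2 = np.append(rad, 0.18)
        after, _ = E.sasa(pos2, rad2)
        assert np.all(after[:12] <= before + 1e-12)

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            E.sasa(np.zeros((1, 3)), [-0.1])

    def test_biotite_cross_check(self, rng):
        """Independent Shrake-Rupley implementation agrees on a random
        cluster."""
        struc = pytest.importorskip("biotite.structure")
        pos = rng.uniform(0, 1.2, (20, 3))
        rad = np.full(20, 0.17)
        _, ours = E.sasa(pos, rad, E.SASAConfig(n_sphere_points=960))
        atoms = struc.AtomArray(20)
        atoms.coord = (pos * 10).astype(np.float32)
        atoms.element = np.full(20, "C")
        theirs = struc.sasa(atoms, probe_radius=1.4, point_number=1000,
                            vdw_radii=np.full(20, 1.7)).sum() / 100.0
        assert ours == pytest.approx(theirs, rel=0.02)


def _toy_dimer_trajectory():
    """4 + 3 atom dimer, three identical frames."""
    pos = np.array([
        [0.0, 0.0, 0.0], [0.15, 0.0, 0.0], [0.0, 0.15, 0.0], [0.0, 0.0, 0.15],
        [0.8, 0.0, 0.0], [0.95, 0.0, 0.0], [0.8, 0.15, 0.0],
    ])
    n = 7
    top = MolecularSystem(
        names=np.array([f"A{i}" for i in range(n)], dtype=object),
        elements=np.full(n, "C", dtype=object),
        groups=np.array(["CNT"] * 4 + ["PEPTIDE"] * 3, dtype=object),
        resids=np.array([0] * 4 + [1] * 3),
        resnames=np.full(n, "TOY", dtype=object),
        positions=pos,
        charges=np.array([0.2, -0.2, 0.1, -0.1, 0.3, -0.2, -0.1]),
        sigmas=np.full(n, 0.30), epsilons=np.full(n, 0.40),
        masses=np.full(n, 12.0), box=6.0)
    frames = np.tile(pos, (3, 1, 1))
    return Trajectory(topology=top, frames=frames, times=np.arange(3.0))


class TestBindingFreeEnergy:
    def test_inert_far_groups_give_zero(self):
        pos = np.array([[0.0, 0, 0], [40.0, 0, 0]])
        top = MolecularSystem(
            names=np.array(["A", "B"], dtype=object),
            elements=np.array(["C", "C"], dtype=object),
            groups=np.array(["CNT", "PEPTIDE"], dtype=object),
            resids=np.array([0, 1]),
            resnames=np.array(["X", "Y"], dtype=object),
            positions=pos, charges=np.zeros(2), sigmas=np.full(2, 0.3),
            epsilons=np.zeros(2), masses=np.full(2, 12.0), box=100.0)
        traj = Trajectory(topology=top, frames=pos[None], times=np.zeros(1))
        out = E.binding_free_energy(traj, [0], [1],
                                    pb=E.PBConfig(grid_spacing=0.1),
                                    frame_window=slice(0, 1))
        assert out.E_vdW[0] == pytest.approx(0.0, abs=1e-9)
        assert out.E_coul[0] == 0.0
        assert out.dG_pol[0] == 0.0          # all charges zero
        assert out.dG_nonpol[0] == pytest.approx(0.0, abs=1e-9)
        assert out.dG_bind[0] == pytest.approx(0.0, abs=1e-9)

    def test_toy_dimer_matches_per_term_oracles(self):
        """The assembled decomposition equals independently composed calls
        of each term on the fixed dimer."""
        traj = _toy_dimer_trajectory()
        top = traj.topology
        rec, lig = np.arange(4), np.arange(4, 7)
        pb = E.PBConfig(grid_spacing=0.1)
        out = E.binding_free_energy(traj, rec, lig, pb=pb,
                                    frame_window=slice(0, 1))
        pos = traj.frames[0]
        evdw = E.lj_energy(pos[rec], top.sigmas[rec], top.epsilons[rec],
                           pos[lig], top.sigmas[lig], top.epsilons[lig])
        ecoul = E.coulomb_energy(pos[rec], top.charges[rec],
                                 pos[lig], top.charges[lig])
        radii = E.pb_radii(top.sigmas)
        gp = (E.solve_pb(pos, top.charges, radii, pb)
              - E.solve_pb(pos[rec], top.charges[rec], radii[rec], pb)
              - E.solve_pb(pos[lig], top.charges[lig], radii[lig], pb))
        cfg = E.SASAConfig()
        gnp = (E.nonpolar_energy(E.sasa(pos, radii, cfg)[1], cfg)
               - E.nonpolar_energy(E.sasa(pos[rec], radii[rec], cfg)[1], cfg)
               - E.nonpolar_energy(E.sasa(pos[lig], radii[lig], cfg)[1], cfg))
        assert out.E_vdW[0] == pytest.approx(evdw, rel=1e-10)
        assert out.E_coul[0] == pytest.approx(ecoul, rel=1e-10)
        assert out.dG_pol[0] == pytest.approx(gp, rel=1e-8)
        assert out.dG_nonpol[0] == pytest.approx(gnp, rel=1e-10)

    def test_decomposition_identity_per_frame(self):
        traj = _toy_dimer_trajectory()
        out = E.binding_free_energy(traj, np.arange(4), np.arange(4, 7),
                                    pb=E.PBConfig(grid_spacing=0.1),
                                    frame_window=slice(0, 3))
        lhs = out.dG_bind
        rhs = out.E_intra + out.E_vdW + out.E_coul + out.dG_pol + out.dG_nonpol
        assert np.allclose(lhs, rhs, atol=1e-12)
        assert np.all(out.E_intra == 0.0)

    def test_overlapping_selections_rejected(self):
        traj = _toy_dimer_trajectory()
        with pytest.raises(ValueError):
            E.binding_free_energy(traj, [0, 1, 2], [2, 3])

    def test_empty_window_rejected(self):
        traj = _toy_dimer_trajectory()
        with pytest.raises(Exception):
            E.binding_free_energy(traj, [0], [4], frame_window=slice(5, 5))
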