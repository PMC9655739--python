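"""Construction arithmetic and fragment builders."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanobrush import builders as B
from nanobrush.core import InvalidSpecError


class TestSetupArithmetic:
    @pytest.mark.parametrize("n,m,a,expect_exact,expect_nominal", [
        (10, 0, 0.246, 0.246 / math.pi * 10, 0.8),
        (1, 0, math.pi, 1.0, 1.0),
        (5, 5, 0.246, 0.246 / math.pi * math.sqrt(75), 0.7),
    ])
    def test_diameter(self, n, m, a, expect_exact, expect_nominal):
        d, nominal = B.cnt_diameter(B.CNTSpec(n=n, m=m, length=4.1, lattice_a=a))
        assert d == pytest.approx(expect_exact, rel=1e-12)
        assert nominal == pytest.approx(expect_nominal)

    def test_diameter_invalid_spec(self):
        with pytest.raises(InvalidSpecError):
            B.CNTSpec(n=0, length=4.1)

    @pytest.mark.parametrize("d,length,expect", [
        (0.8, 4.1, math.pi * 0.8 * 4.1),          # reported as 10.3 nm^2
        (1.0 / math.pi, 1.0, 1.0),
        (0.246 / math.pi * 10, 4.1, math.pi * 0.246 / math.pi * 10 * 4.1),
    ])
    def test_sidewall_area(self, d, length, expect):
        assert B.sidewall_area(d, length) == pytest.approx(expect, rel=1e-12)

    def test_sidewall_area_rejects_nonpositive(self):
        with pytest.raises(InvalidSpecError):
            B.sidewall_area(0.0, 4.1)

    @pytest.mark.parametrize("n_chains,expect_3dp", [(4, 0.388), (8, 0.776),
                                                     (16, 1.553), (0, 0.0)])
    def test_grafting_density(self, n_chains, expect_3dp):
        area = B.sidewall_area(0.8, 4.1)
        assert round(B.grafting_density(n_chains, area), 3) == expect_3dp

    @given(n=st.integers(0, 200), area=st.floats(0.1, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sigma_area_round_trip(self, n, area):
        assert B.grafting_density(n, area) * area == pytest.approx(n, abs=1e-9)


class TestBuildCNT:
    def test_all_atoms_on_cylinder(self, cnt10):
        d, _ = B.cnt_diameter(B.CNTSpec(10, 0, 4.1))
        r = np.hypot(cnt10.positions[:, 0], cnt10.positions[:, 1])
        assert np.all(np.abs(r - d / 2) < 1e-6)

    def test_one_period_atom_count(self):
        one = B.build_cnt(B.CNTSpec(10, 0, 0.43))  # just over one period
        assert one.n_atoms == 40

    def test_neighbour_distances_arc_corrected(self, cnt10):
        # arc-corrected nearest-neighbour distance equals the C-C bond length
        a_cc = 0.246 / math.sqrt(3)
        i0 = cnt10.n_atoms // 2  # interior atom: all three neighbours exist
        r = np.hypot(cnt10.positions[i0, 0], cnt10.positions[i0, 1])
        theta = np.arctan2(cnt10.positions[:, 1], cnt10.positions[:, 0])
        dth = np.abs(np.angle(np.exp(1j * (theta - theta[i0]))))
        arc = np.sqrt((r * dth) ** 2 + (cnt10.positions[:, 2]
                                        - cnt10.positions[i0, 2]) ** 2)
        nn = np.sort(arc)[1:4]
        assert np.all(np.abs(nn - a_cc) / a_cc < 0.01)

    def test_uncharged_single_lj_type_immobile(self, cnt10):
        assert cnt10.total_charge() == 0.0
        assert len(set(cnt10.sigmas)) == 1 and len(set(cnt10.epsilons)) == 1
        assert cnt10.immobile.all()

    def test_deterministic(self):
        a = B.build_cnt(B.CNTSpec(10, 0, 4.1))
        b = B.build_cnt(B.CNTSpec(10, 0, 4.1))
        assert np.array_equal(a.positions, b.positions)

    def test_armchair_rejected(self):
        with pytest.raises(B.UnsupportedChiralityError):
            B.build_cnt(B.CNTSpec(5, 5, 4.1))


class TestBuildPEO:
    @pytest.mark.parametrize("n,expect_heavy", [(18, 55), (1, 4)])
    def test_heavy_atom_count(self, n, expect_heavy):
        chain = B.build_peo_chain(n)
        assert int((chain.elements != "H").sum()) == expect_heavy

    def test_extension_matches_rise(self):
        chain = B.build_peo_chain(18, rise=0.28)
        heavy = chain.positions[chain.elements != "H"]
        ext = heavy[:, 2].max() - heavy[:, 2].min()
        assert abs(ext - 18 * 0.28) / (18 * 0.28) < 0.10

    def test_neutral(self):
        assert B.build_peo_chain(18).total_charge() == pytest.approx(0.0, abs=1e-12)


class TestGrafting:
    def test_four_chains_single_ring_right_angles(self, cnt10):
        g = B.graft_chains(cnt10, B.GraftSpec(n_chains=4), n_rings=1)
        anchors = g.bonds[-4:, 0]  # sidewall carbons
        th = np.sort(np.arctan2(cnt10.positions[anchors, 1],
                                cnt10.positions[anchors, 0]))
        gaps = np.degrees(np.diff(np.concatenate([th, [th[0] + 2 * np.pi]])))
        assert np.allclose(gaps, 90.0, atol=20.0)  # snapped to lattice carbons

    def test_eight_chains_two_rings_symmetric(self, cnt10):
        g = B.graft_chains(cnt10, B.GraftSpec(n_chains=8), n_rings=2)
        anchors = g.bonds[-8:, 0]
        z = cnt10.positions[anchors, 2]
        assert abs(z.mean()) < 0.15  # rings symmetric about the midplane
        assert len(np.unique(np.round(z, 1))) == 2

    def test_sixteen_chains_beat_random_placements(self, cnt10, rng):
        """Even pattern maximises the minimum anchor geodesic separation
        against a 1000-draw random-placement oracle."""
        g = B.graft_chains(cnt10, B.GraftSpec(n_chains=16))
        anchors = g.bonds[-16:, 0]

        def min_geodesic(idx):
            p = cnt10.positions[idx]
            r = np.hypot(p[0, 0], p[0, 1])
            th = np.arctan2(p[:, 1], p[:, 0])
            dth = np.abs(np.angle(np.exp(1j * (th[:, None] - th[None, :]))))
            d = np.sqrt((r * dth) ** 2 + (p[:, 2, None] - p[None, :, 2]) ** 2)
            iu = np.triu_indices(len(idx), 1)
            return d[iu].min()

        ours = min_geodesic(anchors)
        best_random = max(
            min_geodesic(rng.choice(cnt10.n_atoms, 16, replace=False))
            for _ in range(1000))
        assert ours >= best_random

    def test_capacity_error(self, cnt10):
        with pytest.raises(B.CapacityError):
            B.graft_chains(cnt10, B.GraftSpec(n_chains=997))

    def test_zero_chains_is_identity(self, cnt10):
        g = B.graft_chains(cnt10, B.GraftSpec(n_chains=0))
        assert g.n_atoms == cnt10.n_atoms


class TestHomopeptide:
    @pytest.mark.parametrize("res,nres,expect", [
        ("GLY", 24, 24 * 7 + 3),
        ("SER", 24, 24 * 11 + 3),
        ("VAL", 24, 24 * 16 + 3),
        ("VAL", 1, 16 + 3),
    ])
    def test_atom_counts(self, res, nres, expect):
        p = B.build_homopeptide(B.PeptideSpec(res, nres))
        assert p.n_atoms == expect

    @pytest.mark.parametrize("res", ["GLY", "SER", "VAL"])
    def test_zwitterion_net_charge(self, res):
        p = B.build_homopeptide(B.PeptideSpec(res, 12))
        assert p.total_charge() == pytest.approx(0.0, abs=1e-9)
        # N-terminal residue carries +1, C-terminal -1
        q0 = p.charges[p.resids == 0].sum()
        qn = p.charges[p.resids == 11].sum()
        assert q0 == pytest.approx(1.0, abs=1e-9)
        assert qn == pytest.approx(-1.0, abs=1e-9)

    def test_unknown_residue(self):
        with pytest.raises(InvalidSpecError):
            B.PeptideSpec("ALA", 24)


class TestHydropathy:
    @pytest.mark.parametrize("res,expect", [("VAL", 4.2), ("GLY", -0.4),
                                            ("SER", -0.8)])
    def test_printed_values(self, res, expect):
        assert B.lookup_hydropathy(res) == expect

    def test_unknown_key(self):
        with pytest.raises(KeyError):
            B.lookup_hydropathy("XYZ")


class TestPlacement:
    def test_gap_band(self, grafted8, gly24):
        from scipy.spatial import cKDTree
        sys8 = grafted8.copy()
        sys8.box = 12.0
        full = B.place_peptide(sys8, gly24, gap=0.3)
        pep = full.positions[full.groups == "PEPTIDE"]
        layer = full.positions[full.groups != "PEPTIDE"]
        d = cKDTree(layer).query(pep)[0].min()
        assert 0.30 <= d <= 0.32

    def test_box_too_small(self, cnt10, gly24):
        small = cnt10.copy()
        small.box = 1.0
        with pytest.raises(B.PlacementError):
            B.place_peptide(small, gly24, gap=0.3)


class TestSolvent:
    def test_empty_box_density(self):
        w = B.solvate(None, B.SolventSpec(box_edge=6.0))
        n = len(np.unique(w.resids))
        assert n == round(33.3 * 6.0 ** 3)       # 7193
        assert abs(n / 6.0 ** 3 - 33.3) / 33.3 < 0.03

    def test_pristine_cnt_water_count(self, cnt10):
        sys6 = cnt10.copy()
        sys6.box = 6.0
        s = B.solvate(sys6, B.SolventSpec(box_edge=6.0))
        n = len(np.unique(s.resids[s.groups == "WATER"]))
        assert abs(n - 7010) / 7010 < 0.05

    def test_full_exclusion_removes_everything(self, cnt10):
        s = B.solvate(cnt10, B.SolventSpec(box_edge=6.0, exclusion_radius=6.0))
        assert int((s.groups == "WATER").sum()) == 0

    def test_determinism(self):
        a = B.solvate(None, B.SolventSpec(box_edge=4.0), seed=7)
        b = B.solvate(None, B.SolventSpec(box_edge=4.0), seed=7)
        assert np.array_equal(a.positions, b.positions)


class TestIons:
    def test_physiological_pair_count(self):
        water = B.solvate(None, B.SolventSpec(box_edge=6.0))
        out = B.add_ions(water, 9.0, seed=0)
        n_na = int((out.groups == "NA").sum())
        n_cl = int((out.groups == "CL").sum())
        # c = 9.0/58.44 = 0.154 M; V = 7193/33.3 nm^3 -> 20 pairs
        assert n_na == n_cl == 20
        assert out.total_charge() == pytest.approx(0.0, abs=1e-9)

    def test_zero_concentration_unchanged(self):
        water = B.solvate(None, B.SolventSpec(box_edge=4.0))
        out = B.add_ions(water, 0.0)
        assert out.n_atoms == water.n_atoms

    def test_too_few_waters(self):
        water = B.solvate(None, B.SolventSpec(box_edge=4.0))
        keep = water.resids < 3   # keep 3 molecules
        tiny = water.subset(np.flatnonzero(keep))
        with pytest.raises(B.CompositionError):
            B.add_ions(tiny, 5000.0)
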