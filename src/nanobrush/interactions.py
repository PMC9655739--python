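"""Hydrogen bonds, sodium bridges, backbone dihedrals, secondary structure.

A hydrogen bond is defined purely geometrically: donor--acceptor distance at
most 0.35 nm and at most 30 degrees deviation from linearity.  The default
angular convention measures the angle between the D->H and D->A vectors (the
common MD-package choice); the alternative 180 - angle(D-H...A) convention is
available via :class:`HBondCriterion`.

Secondary structure is assigned from explicit backbone hydrogen-bond
patterns (helices from consecutive i->i+4 / i->i+3 bonds, bridges and sheets
from long-range bonds, turns from isolated short-range bonds).  This is a
documented stand-in for energy/propensity-based assigners such as STRIDE;
the six class labels match the conventional ones so reports are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    EmptyInputError, GROUP_PEO, GROUP_PEPTIDE, GROUP_WATER, MolecularSystem,
    NanobrushError, Trajectory,
)

__all__ = [
    "HBondCriterion", "HBondRecord", "hbond_topology", "detect_hbonds",
    "find_hbonds", "hbond_summary", "detect_ion_bridges",
    "backbone_dihedrals", "assign_secondary_structure", "dihedral_angle",
    "TopologyError", "CATEGORIES",
]

CATEGORIES = ("intra-peptide", "peptide-water", "peptide-PEO", "PEO-water", "other")


class TopologyError(NanobrushError, ValueError):
    """Missing covalent information (unbonded hydrogen, absent backbone atom)."""


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    max_da_distance : nm, donor--acceptor heavy-atom cutoff (default 0.35).
    max_angle_deviation : degrees of allowed deviation from linearity
        (default 30).
    angle_convention : 'donor' measures angle(D->H, D->A); 'dha' measures
        180 - angle(D-H...A).
    """

    max_da_distance: float = 0.35
    max_angle_deviation: float = 30.0
    angle_convention: str = "donor"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_angle_deviation <= 0:
            raise ValueError("criterion thresholds must be positive")
        if self.angle_convention not in ("donor", "dha"):
            raise ValueError("angle_convention must be 'donor' or 'dha'")


@dataclass
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    d_da: float
    angle_dev: float
    category: str = "other"


# ---------------------------------------------------------------------------
# Topology-derived donor/acceptor chemistry
# ---------------------------------------------------------------------------

def hbond_topology(system: MolecularSystem
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Donor (heavy, hydrogen) pairs and acceptor indices from bonds.

    Donors are N-H and O-H covalent pairs (backbone amides, the protonated
    N-terminus, serine hydroxyls, water).  Acceptors are all oxygen atoms:
    carbonyl, carboxylate, hydroxyl, water, and PEO ether oxygens (PEO has
    no donors).  A hydrogen bonded to no heavy atom raises TopologyError.
    """
    is_h = system.elements == "H"
    donor_of = {}
    for a, b in system.bonds:
        for h, heavy in ((a, b), (b, a)):
            if is_h[h] and system.elements[heavy] in ("N", "O"):
                donor_of[int(h)] = int(heavy)
    orphan = [int(i) for i in np.flatnonzero(is_h)
              if int(i) not in donor_of
              and not _has_bond(system, int(i))]
    if orphan:
        raise TopologyError(f"hydrogens without a bonded donor: {orphan[:10]}")
    donors = np.array([[heavy, h] for h, heavy in sorted(donor_of.items())],
                      dtype=int).reshape(-1, 2)
    acceptors = np.flatnonzero(system.elements == "O")
    return donors, acceptors


def _has_bond(system: MolecularSystem, i: int) -> bool:
    return bool(len(system.bonds)) and bool(np.any(system.bonds == i))


def _excluded_pairs(system: MolecularSystem) -> set[tuple[int, int]]:
    """(heavy, acceptor) pairs within two covalent bonds; these are never
    counted as hydrogen bonds."""
    adj: dict[int, set[int]] = {}
    for a, b in system.bonds:
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    excluded = set()
    for i in adj:
        first = adj[i]
        second = set().union(*(adj.get(j, set()) for j in first)) if first else set()
        for j in first | second | {i}:
            excluded.add((i, j))
    return excluded


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_hbonds(positions: np.ndarray, donors: np.ndarray,
                  acceptors: np.ndarray,
                  criterion: HBondCriterion | None = None,
                  excluded: set[tuple[int, int]] | None = None,
                  frame: int = 0) -> list[HBondRecord]:
    """All hydrogen bonds in one frame.

    ``donors`` is an (n, 2) array of (heavy, hydrogen) index pairs,
    ``acceptors`` an index array of acceptor heavy atoms.  Candidate pairs
    are found with a KD-tree on the acceptor coordinates; the result is
    identical to the all-pairs computation.
    """
    crit = criterion or HBondCriterion()
    donors = np.asarray(donors, dtype=int).reshape(-1, 2)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    tree = cKDTree(positions[acceptors])
    neighbours = tree.query_ball_point(positions[donors[:, 0]],
                                       crit.max_da_distance)
    records = []
    for di, acc_list in enumerate(neighbours):
        d_idx, h_idx = int(donors[di, 0]), int(donors[di, 1])
        for ai in acc_list:
            a_idx = int(acceptors[ai])
            if a_idx == d_idx:
                continue
            if excluded and (d_idx, a_idx) in excluded:
                continue
            da = positions[a_idx] - positions[d_idx]
            d_da = float(np.linalg.norm(da))
            if d_da > crit.max_da_distance:
                continue
            dh = positions[h_idx] - positions[d_idx]
            if crit.angle_convention == "donor":
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * d_da)
                dev = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            else:
                ha = positions[a_idx] - positions[h_idx]
                hd = -dh
                cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                dev = 180.0 - float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if dev <= crit.max_angle_deviation:
                records.append(HBondRecord(frame=frame, donor=d_idx,
                                           hydrogen=h_idx, acceptor=a_idx,
                                           d_da=d_da, angle_dev=dev))
    return records


def _categorize(system: MolecularSystem, rec: HBondRecord) -> str:
    pair = frozenset((str(system.groups[rec.donor]),
                      str(system.groups[rec.acceptor])))
    if pair == frozenset((GROUP_PEPTIDE,)):
        return "intra-peptide"
    if pair == frozenset((GROUP_PEPTIDE, GROUP_WATER)):
        return "peptide-water"
    if pair == frozenset((GROUP_PEPTIDE, GROUP_PEO)):
        return "peptide-PEO"
    if pair == frozenset((GROUP_PEO, GROUP_WATER)):
        return "PEO-water"
    return "other"


def find_hbonds(system: MolecularSystem, positions: np.ndarray | None = None,
                criterion: HBondCriterion | None = None,
                frame: int = 0) -> list[HBondRecord]:
    """Detect and categorise hydrogen bonds of a full system in one frame."""
    pos = system.positions if positions is None else positions
    donors, acceptors = hbond_topology(system)
    excluded = _excluded_pairs(system)
    records = detect_hbonds(pos, donors, acceptors, criterion, excluded, frame)
    # one bond per unique donor-heavy/acceptor pair (a symmetric pair of
    # O-H...O bonds between the same two oxygens still counts twice only if
    # both directions are real donor-H geometries)
    for rec in records:
        rec.category = _categorize(system, rec)
    return records


def hbond_summary(traj: Trajectory,
                  criterion: HBondCriterion | None = None) -> pd.DataFrame:
    """Mean +/- sd hydrogen-bond counts per category over a trajectory."""
    if traj.n_frames == 0:
        raise EmptyInputError("empty trajectory")
    donors, acceptors = hbond_topology(traj.topology)
    excluded = _excluded_pairs(traj.topology)
    counts = {cat: np.zeros(traj.n_frames) for cat in CATEGORIES}
    for f in range(traj.n_frames):
        records = detect_hbonds(traj.frames[f], donors, acceptors, criterion,
                                excluded, frame=f)
        for rec in records:
            counts[_categorize(traj.topology, rec)][f] += 1
    return pd.DataFrame({
        "category": CATEGORIES,
        "mean": [counts[c].mean() for c in CATEGORIES],
        "sd": [counts[c].std(ddof=0) for c in CATEGORIES],
    }).set_index("category")


# ---------------------------------------------------------------------------
# Sodium bridges
# ---------------------------------------------------------------------------

def detect_ion_bridges(positions: np.ndarray, cations, o_peo, o_pep,
                       cutoff: float = 0.32
                       ) -> tuple[int, list[tuple[int, int, int]]]:
    """Cations simultaneously within ``cutoff`` of a PEO oxygen and a
    peptide oxygen.  Returns (bridge count, one (cation, O_peo, O_pep)
    triple per bridging cation, nearest oxygens)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cations = np.asarray(cations, dtype=int)
    o_peo = np.asarray(o_peo, dtype=int)
    o_pep = np.asarray(o_pep, dtype=int)
    triples = []
    if len(cations) == 0 or len(o_peo) == 0 or len(o_pep) == 0:
        return 0, triples
    t_peo = cKDTree(positions[o_peo])
    t_pep = cKDTree(positions[o_pep])
    d1, i1 = t_peo.query(positions[cations])
    d2, i2 = t_pep.query(positions[cations])
    for k in range(len(cations)):
        if d1[k] <= cutoff and d2[k] <= cutoff:
            triples.append((int(cations[k]), int(o_peo[i1[k]]),
                            int(o_pep[i2[k]])))
    return len(triples), triples


# ---------------------------------------------------------------------------
# Backbone dihedrals and secondary structure
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, degrees in (-180, 180], IUPAC
    convention (cis = 0)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def _backbone_index(system: MolecularSystem) -> dict[tuple[int, str], int]:
    out = {}
    pep = system.groups == GROUP_PEPTIDE
    for i in np.flatnonzero(pep):
        nm = str(system.names[i])
        if nm in ("N", "CA", "C", "O", "H"):
            out[(int(system.resids[i]), nm)] = int(i)
    return out


def backbone_dihedrals(system: MolecularSystem,
                       positions: np.ndarray | None = None) -> np.ndarray:
    """Per-residue (phi, psi) in degrees; NaN where undefined (chain ends).

    phi_i = C(i-1)-N(i)-CA(i)-C(i); psi_i = N(i)-CA(i)-C(i)-N(i+1).
    """
    pos = system.positions if positions is None else positions
    bb = _backbone_index(system)
    if not bb:
        raise EmptyInputError("system contains no peptide backbone")
    resids = sorted({r for r, _ in bb})
    lo, hi = resids[0], resids[-1]
    for r in range(lo, hi + 1):
        for nm in ("N", "CA", "C"):
            if (r, nm) not in bb:
                raise TopologyError(f"missing backbone atom {nm} in residue {r}")
    out = np.full((hi - lo + 1, 2), np.nan)
    for r in range(lo, hi + 1):
        i = r - lo
        if r > lo:
            out[i, 0] = dihedral_angle(pos[bb[(r - 1, "C")]], pos[bb[(r, "N")]],
                                       pos[bb[(r, "CA")]], pos[bb[(r, "C")]])
        if r < hi:
            out[i, 1] = dihedral_angle(pos[bb[(r, "N")]], pos[bb[(r, "CA")]],
                                       pos[bb[(r, "C")]], pos[bb[(r + 1, "N")]])
    return out


#: One-letter codes used in assignments.
SS_CODES = {"alpha-helix": "H", "310-helix": "G", "beta-sheet": "E",
            "isolated-bridge": "B", "turn": "T", "coil": "C"}


def assign_secondary_structure(system: MolecularSystem,
                               positions: np.ndarray | None = None,
                               criterion: HBondCriterion | None = None
                               ) -> np.ndarray:
    """Per-residue secondary-structure labels from backbone H-bond patterns.

    Priority rules: two consecutive i->i+4 backbone bonds make an
    alpha-helix (H) over residues i+1..i+4; two consecutive i->i+3 bonds a
    3-10 helix (G); long-range (|i-j| > 4) bonds define bridges, adjacent
    bridges merge into beta-sheet (E), single ones stay isolated bridges
    (B); an unextended i->i+3/4/5 bond marks a turn (T); everything else is
    coil (C).  Exactly one label per residue.
    """
    pos = system.positions if positions is None else positions
    bb = _backbone_index(system)
    resids = sorted({r for r, _ in bb})
    nres = len(resids)
    if nres < 5:
        raise TopologyError("secondary structure needs at least 5 residues")
    lo = resids[0]

    # backbone-only hydrogen bonds: carbonyl O (acceptor, residue i) to
    # amide H-N (donor, residue j)
    donors = np.array([[bb[(r, "N")], bb[(r, "H")]] for r in resids
                       if (r, "H") in bb], dtype=int).reshape(-1, 2)
    acceptors = np.array([bb[(r, "O")] for r in resids if (r, "O") in bb],
                         dtype=int)
    res_of = {bb[(r, "N")]: r - lo for r in resids if (r, "H") in bb}
    res_of.update({bb[(r, "O")]: r - lo for r in resids if (r, "O") in bb})
    records = detect_hbonds(pos, donors, acceptors, criterion)
    bonds = {(res_of[rec.acceptor], res_of[rec.donor]) for rec in records}

    def has(i: int, sep: int) -> bool:
        return (i, i + sep) in bonds

    labels = np.full(nres, "", dtype=object)

    def mark(rng, code):
        for i in rng:
            if 0 <= i < nres and labels[i] == "":
                labels[i] = code

    for i in range(nres):           # alpha helix: >= 2 consecutive i->i+4
        if has(i, 4) and has(i + 1, 4):
            mark(range(i + 1, i + 6), "H")
    for i in range(nres):           # 3-10 helix: >= 2 consecutive i->i+3
        if has(i, 3) and has(i + 1, 3):
            mark(range(i + 1, i + 5), "G")
    bridge_pairs = sorted({(min(i, j), max(i, j)) for (i, j) in bonds
                           if abs(i - j) > 4})
    bridge_set = set(bridge_pairs)
    for (i, j) in bridge_pairs:     # sheets: adjacent bridges
        if ((i + 1, j - 1) in bridge_set or (i + 1, j + 1) in bridge_set
                or (i - 1, j - 1) in bridge_set or (i - 1, j + 1) in bridge_set):
            mark([i, j], "E")
    for (i, j) in bridge_pairs:
        mark([i, j], "B")
    for i in range(nres):           # turns: isolated short-range bonds
        for sep in (3, 4, 5):
            if has(i, sep):
                mark(range(i + 1, i + sep), "T")
    labels[labels == ""] = "C"
    return labels
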