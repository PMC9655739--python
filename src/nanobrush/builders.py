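"""Deterministic construction of PEO-grafted carbon-nanotube / peptide systems.

The builders produce every component of the simulated systems from a handful
of integers and lengths:

* a zigzag ``(n, 0)`` single-walled carbon nanotube obtained by rolling an
  ideal graphene sheet (lattice constant ``a``, default 0.246 nm),
* poly(ethylene oxide) chains in a stretched 7/2-helix starting geometry,
  anchored radially to sidewall carbons on an even deterministic pattern,
* homopeptides (polyglycine, polyserine, polyvaline) built atom by atom from
  ideal internal coordinates at a requested backbone conformation, with a
  protonated N-terminus and a dissociated (carboxylate) C-terminus,
* three-site rigid water on a jittered lattice and Na+/Cl- at a requested
  NaCl mass concentration.

All stochastic steps (lattice jitter, water orientations, ion substitution,
site choice) take an explicit integer seed and are bit-reproducible.

Setup arithmetic (diameter, sidewall area, grafting density, ion counts)
lives here too, because those numbers define the systems being built.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import (
    ELEMENT_MASSES, GROUP_CL, GROUP_CNT, GROUP_NA, GROUP_PEO, GROUP_PEPTIDE,
    GROUP_WATER, InvalidSpecError, MolecularSystem, NA_PER_NM3,
)

__all__ = [
    "CNTSpec", "GraftSpec", "PeptideSpec", "SolventSpec",
    "cnt_diameter", "sidewall_area", "grafting_density",
    "build_cnt", "build_peo_chain", "graft_chains", "build_homopeptide",
    "lookup_hydropathy", "place_peptide", "solvate", "add_ions",
    "UnsupportedChiralityError", "CapacityError", "PlacementError",
    "CompositionError", "RESIDUE_ATOM_COUNTS", "KYTE_DOOLITTLE",
]


class UnsupportedChiralityError(InvalidSpecError):
    """Only zigzag (m = 0) tubes are constructible."""


class CapacityError(InvalidSpecError):
    """More grafted chains requested than the sidewall pattern can host."""


class PlacementError(InvalidSpecError):
    """No non-overlapping peptide placement exists inside the box."""


class CompositionError(InvalidSpecError):
    """Ion substitution would require more waters than are present."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class CNTSpec:
    """Zigzag nanotube: chirality ``(n, 0)``, length in nm, graphene lattice
    constant in nm (C-C bond = lattice_a / sqrt(3))."""

    n: int
    m: int = 0
    length: float = 4.1
    lattice_a: float = 0.246

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidSpecError(f"chirality index n must be >= 1, got {self.n}")
        if self.m < 0:
            raise InvalidSpecError(f"chirality index m must be >= 0, got {self.m}")
        if self.length <= 0:
            raise InvalidSpecError("tube length must be positive")
        if self.lattice_a <= 0:
            raise InvalidSpecError("lattice constant must be positive")


@dataclass
class GraftSpec:
    """Number and size of grafted PEO chains.

    ``sigma`` (chains per nm^2) is derived when omitted; when given it is
    checked against n_chains / area at graft time.
    """

    n_chains: int
    n_monomers: int = 18
    sigma: float | None = None
    terminal: str = "methoxy"

    def __post_init__(self) -> None:
        if self.n_chains < 0:
            raise InvalidSpecError("n_chains must be non-negative")
        if self.n_monomers < 1:
            raise InvalidSpecError("n_monomers must be >= 1")


@dataclass
class PeptideSpec:
    """A homopeptide of one residue type, protonated N-terminus (NH3+) and
    dissociated C-terminus (COO-).  ``conformation`` is the backbone
    (phi, psi) pair in degrees applied uniformly (default extended beta)."""

    residue: str = "GLY"
    n_residues: int = 24
    n_terminus: str = "protonated"
    c_terminus: str = "dissociated"
    conformation: tuple[float, float] = (-135.0, 135.0)

    def __post_init__(self) -> None:
        self.residue = self.residue.upper()
        if self.residue not in RESIDUE_ATOM_COUNTS:
            raise InvalidSpecError(
                f"unknown residue {self.residue!r}; supported: GLY, SER, VAL")
        if self.n_residues < 1:
            raise InvalidSpecError("n_residues must be >= 1")
        if self.n_terminus != "protonated" or self.c_terminus != "dissociated":
            raise InvalidSpecError("termini states are fixed: protonated N, dissociated C")


@dataclass
class SolventSpec:
    """Cubic box, bulk water number density (nm^-3), NaCl mass concentration
    (g/dm^3) and the minimum solvent--solute heavy-atom distance."""

    box_edge: float = 6.0
    water_number_density: float = 33.3
    nacl_mass_conc: float = 0.0
    exclusion_radius: float = 0.26

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise InvalidSpecError("box_edge must be positive")
        if self.nacl_mass_conc < 0:
            raise InvalidSpecError("nacl_mass_conc must be >= 0")


# ---------------------------------------------------------------------------
# Setup arithmetic
# ---------------------------------------------------------------------------

def cnt_diameter(spec: CNTSpec) -> tuple[float, float]:
    """Tube diameter d = (a/pi) sqrt(n^2 + n m + m^2), nm.

    Returns ``(exact, nominal)`` where *nominal* is the value rounded to one
    decimal; the rounded diameter is the one used in the reported sidewall
    area and grafting densities (report-parity convention).
    """
    n, m = spec.n, spec.m
    d = spec.lattice_a / math.pi * math.sqrt(n * n + n * m + m * m)
    return d, round(d, 1)


def sidewall_area(diameter: float, length: float) -> float:
    """Cylindrical sidewall area pi * d * L (nm^2)."""
    if diameter <= 0 or length <= 0:
        raise InvalidSpecError("diameter and length must be positive")
    return math.pi * diameter * length


def grafting_density(n_chains: int, area: float) -> float:
    """Chains per unit sidewall area, sigma = n_chains / area (nm^-2)."""
    if n_chains < 0:
        raise InvalidSpecError("n_chains must be >= 0")
    if area <= 0:
        raise InvalidSpecError("area must be positive")
    return n_chains / area


# ---------------------------------------------------------------------------
# Nanotube
# ---------------------------------------------------------------------------

# OPLS aromatic-carbon LJ parameters used for the uncharged tube carbons.
_CNT_SIGMA, _CNT_EPS = 0.355, 0.29288


def build_cnt(spec: CNTSpec) -> MolecularSystem:
    """Roll a graphene sheet into an uncapped zigzag tube.

    Every carbon lies exactly on the cylinder of radius d/2; the tube axis is
    z and the tube is centered on the origin.  The translational period of a
    zigzag tube is 3 * a_cc = sqrt(3) * a; each complete period contributes
    4n atoms (four rings of n).  Carbons are uncharged, share one LJ type,
    and are flagged immobile.
    """
    if spec.m != 0:
        raise UnsupportedChiralityError(
            f"only zigzag (m = 0) tubes supported, got m = {spec.m}")
    a_cc = spec.lattice_a / math.sqrt(3.0)
    period = 3.0 * a_cc
    n_periods = int(math.floor(spec.length / period + 1e-9))
    if n_periods < 1:
        raise InvalidSpecError(
            f"tube length {spec.length} nm shorter than one period ({period:.4f} nm)")
    radius = cnt_diameter(spec)[0] / 2.0
    n = spec.n

    # Four rings per period at z = 0, a_cc, 1.5 a_cc, 2.5 a_cc; the upper two
    # rings are rotated by half the angular spacing (honeycomb registry).
    ring_z = np.array([0.0, a_cc, 1.5 * a_cc, 2.5 * a_cc])
    ring_off = np.array([0.0, 0.0, math.pi / n, math.pi / n])

    coords = []
    for p in range(n_periods):
        for rz, ro in zip(ring_z, ring_off):
            theta = 2.0 * math.pi * np.arange(n) / n + ro
            z = p * period + rz
            coords.append(np.column_stack([
                radius * np.cos(theta), radius * np.sin(theta),
                np.full(n, z)]))
    pos = np.vstack(coords)
    pos[:, 2] -= n_periods * period / 2.0  # center axially on the origin

    n_atoms = pos.shape[0]
    return MolecularSystem(
        names=np.array([f"C{i + 1}" for i in range(n_atoms)], dtype=object),
        elements=np.full(n_atoms, "C", dtype=object),
        groups=np.full(n_atoms, GROUP_CNT, dtype=object),
        resids=np.zeros(n_atoms, dtype=int),
        resnames=np.full(n_atoms, "CNT", dtype=object),
        positions=pos,
        charges=np.zeros(n_atoms),
        sigmas=np.full(n_atoms, _CNT_SIGMA),
        epsilons=np.full(n_atoms, _CNT_EPS),
        masses=np.full(n_atoms, ELEMENT_MASSES["C"]),
        box=max(2.0 * spec.length, 6.0),
        immobile=np.ones(n_atoms, dtype=bool),
    )


# ---------------------------------------------------------------------------
# PEO chain
# ---------------------------------------------------------------------------

_PEO_PARAMS = {  # name prefix -> (charge, sigma, epsilon)
    "C": (0.20, 0.350, 0.276),
    "O": (-0.40, 0.290, 0.586),
    "H": (0.00, 0.250, 0.1255),
}

#: Heavy atoms per PEO chain of N monomers: (C, C, O) x N plus terminal CH3 carbon.
def peo_heavy_atom_count(n_monomers: int) -> int:
    return 3 * n_monomers + 1


def build_peo_chain(n_monomers: int = 18, terminal: str = "methoxy",
                    rise: float = 0.28) -> MolecularSystem:
    """All-atom (-CH2-CH2-O-)_N chain in a stretched 7/2-helix geometry.

    The helix axis is z; the default rise of 0.28 nm per monomer matches the
    crystalline PEO 7/2 helix (7 monomers per 2 turns).  Atom 0 (the first
    methylene carbon) is the designated anchor for grafting.  Hydrogens are
    included; the heavy-atom composition is 3 N + 1 (terminal methyl carbon
    of the methoxy end group).
    """
    if n_monomers < 1:
        raise InvalidSpecError("n_monomers must be >= 1")
    if terminal != "methoxy":
        raise InvalidSpecError(f"unsupported terminal group {terminal!r}")

    helix_r = 0.15
    dtheta = 2.0 * (2.0 * math.pi / 7.0)  # 7/2 helix: two turns per 7 monomers

    names, charges, positions, bonds = [], [], [], []

    def backbone_pos(t: float) -> np.ndarray:
        ang = t * dtheta
        return np.array([helix_r * math.cos(ang), helix_r * math.sin(ang), t * rise])

    def add_atom(name: str, pos: np.ndarray, charge: float) -> int:
        names.append(name)
        charges.append(charge)
        positions.append(pos)
        return len(names) - 1

    def add_hydrogens(c_idx: int, pos: np.ndarray, count: int) -> None:
        radial = np.array([pos[0], pos[1], 0.0])
        nr = np.linalg.norm(radial)
        u = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
        t = np.cross([0.0, 0.0, 1.0], u)
        dirs = [u + 0.8 * t, u - 0.8 * t, u + 0.8 * np.array([0.0, 0.0, 1.0])]
        for j in range(count):
            d = dirs[j] / np.linalg.norm(dirs[j])
            h = add_atom("H", pos + 0.109 * d, _PEO_PARAMS["H"][0])
            bonds.append((c_idx, h))

    prev = None
    for mono in range(n_monomers):
        for j, nm in enumerate(("C1", "C2", "O")):
            pos = backbone_pos(mono + j / 3.0)
            q = _PEO_PARAMS[nm[0]][0]
            if mono == 0 and j == 0:
                q = 0.0  # anchor carbon: bonded to the tube, not to an ether O
            idx = add_atom(nm, pos, q)
            if prev is not None:
                bonds.append((prev, idx))
            if nm != "O":
                add_hydrogens(idx, pos, 2)
            prev = idx
    # terminal methoxy carbon
    pos = backbone_pos(float(n_monomers))
    cm = add_atom("CM", pos, _PEO_PARAMS["C"][0])
    bonds.append((prev, cm))
    add_hydrogens(cm, pos, 3)

    n_atoms = len(names)
    elements = np.array([("C" if nm.startswith("C") else nm[0]) for nm in names],
                        dtype=object)
    sig = np.array([_PEO_PARAMS[e if e in _PEO_PARAMS else "C"][1] for e in elements])
    eps = np.array([_PEO_PARAMS[e if e in _PEO_PARAMS else "C"][2] for e in elements])
    return MolecularSystem(
        names=np.array(names, dtype=object),
        elements=elements,
        groups=np.full(n_atoms, GROUP_PEO, dtype=object),
        resids=np.zeros(n_atoms, dtype=int),
        resnames=np.full(n_atoms, "PEO", dtype=object),
        positions=np.vstack(positions),
        charges=np.array(charges),
        sigmas=sig,
        epsilons=eps,
        masses=np.array([ELEMENT_MASSES[e] for e in elements]),
        box=max(4.0, 2.0 * n_monomers * rise),
        bonds=np.array(bonds, dtype=int),
    )


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------

def _pattern_sites(r: int, k: int, radius: float, span: float) -> np.ndarray:
    """Ideal (theta, z) anchor sites of an r-rings x k-slots pattern."""
    out = []
    for i in range(r):
        zc = (i + 0.5) / r * span - span / 2.0
        for j in range(k):
            out.append((2.0 * math.pi * j / k + (i % 2) * math.pi / k, zc))
    return np.array(out)


def _min_geodesic(sites: np.ndarray, radius: float) -> float:
    th, z = sites[:, 0], sites[:, 1]
    dth = np.abs(np.angle(np.exp(1j * (th[:, None] - th[None, :]))))
    d = np.sqrt((radius * dth) ** 2 + (z[:, None] - z[None, :]) ** 2)
    iu = np.triu_indices(len(sites), 1)
    return float(d[iu].min())


def _grafting_pattern(n_chains: int, n_slots: int, n_periods: int,
                      n_rings: int | None, radius: float,
                      span: float) -> tuple[int, int]:
    """Choose (rings, chains per ring).

    Default rule: among the divisor patterns r x k = n_chains that fit the
    tube (k angular slots per carbon ring, r rings along the axis), pick the
    one whose ideal sites maximise the minimum pairwise geodesic separation
    -- the deterministic reading of "evenly distributed".  Ties go to fewer
    rings.  An explicit ring count overrides the rule.
    """
    if n_rings is not None:
        if n_chains % n_rings:
            raise CapacityError(
                f"{n_chains} chains not divisible into {n_rings} rings")
        r, k = n_rings, n_chains // n_rings
        if k > n_slots or r > n_periods:
            raise CapacityError(
                f"pattern {r} rings x {k} slots exceeds tube capacity")
        return r, k
    best = None
    for r in range(1, n_chains + 1):
        if n_chains % r:
            continue
        k = n_chains // r
        if k > n_slots or r > n_periods:
            continue
        if n_chains == 1:
            return 1, 1
        score = _min_geodesic(_pattern_sites(r, k, radius, span), radius)
        if best is None or score > best[0] + 1e-12:
            best = (score, r, k)
    if best is None:
        raise CapacityError(
            f"cannot place {n_chains} chains on a tube with {n_slots} angular "
            f"slots and {n_periods} periods")
    return best[1], best[2]


def graft_chains(cnt: MolecularSystem, graft: GraftSpec,
                 orientation: str = "radial",
                 n_rings: int | None = None) -> MolecularSystem:
    """Anchor ``graft.n_chains`` PEO chains radially on the tube sidewall.

    Anchor carbons follow a deterministic even pattern of r rings times k
    angular slots (r * k = n_chains), adjacent rings rotated by half an
    angular spacing.  Each chain is rigidly rotated so its helix axis points
    along the outward radial direction of its anchor carbon and a bond
    record links the anchor methylene carbon to the sidewall carbon.
    """
    if orientation != "radial":
        raise InvalidSpecError(f"unsupported orientation {orientation!r}")
    if graft.n_chains == 0:
        return cnt.copy()

    cnt_pos = cnt.positions
    radius = float(np.hypot(cnt_pos[:, 0], cnt_pos[:, 1]).mean())
    z_vals = np.unique(np.round(cnt_pos[:, 2], 6))
    # angular slots per ring = atoms in the lowest ring; periods = rings / 4
    n_slots = int(np.sum(np.isclose(cnt_pos[:, 2], z_vals[0], atol=1e-6)))
    n_periods = max(1, len(z_vals) // 4)
    span0 = float(cnt_pos[:, 2].max() - cnt_pos[:, 2].min())
    r_rings, k = _grafting_pattern(graft.n_chains, n_slots, n_periods, n_rings,
                                   radius, span0)

    if graft.sigma is not None:
        area = sidewall_area(2.0 * radius, z_vals[-1] - z_vals[0] + 1e-12)
        if abs(graft.sigma * area - graft.n_chains) / max(graft.n_chains, 1) > 0.25:
            warnings.warn(
                "GraftSpec.sigma inconsistent with n_chains / sidewall area",
                stacklevel=2)

    z_lo, z_hi = cnt_pos[:, 2].min(), cnt_pos[:, 2].max()
    span = z_hi - z_lo
    ring_z = z_lo + (np.arange(r_rings) + 0.5) / r_rings * span

    chain_template = build_peo_chain(graft.n_monomers, graft.terminal)
    fragments = [cnt.copy()]
    anchor_bonds = []
    used: set[int] = set()
    offset = cnt.n_atoms
    for i, zc in enumerate(ring_z):
        for j in range(k):
            theta = 2.0 * math.pi * j / k + (i % 2) * math.pi / k
            target = np.array([radius * math.cos(theta),
                               radius * math.sin(theta), zc])
            order = np.argsort(np.linalg.norm(cnt_pos - target, axis=1))
            carbon = next(int(c) for c in order if int(c) not in used)
            used.add(carbon)
            cpos = cnt_pos[carbon]
            u = np.array([cpos[0], cpos[1], 0.0])
            u /= np.linalg.norm(u)
            rot = _rotation_z_to(u)
            chain = chain_template.copy()
            chain.positions = chain.positions @ rot.T
            anchor = chain.positions[0].copy()
            chain.positions += cpos + 0.15 * u - anchor
            fragments.append(chain)
            anchor_bonds.append((carbon, offset))
            offset += chain.n_atoms
    out = MolecularSystem.concat(fragments, box=cnt.box)
    out.bonds = np.vstack([out.bonds, np.array(anchor_bonds, dtype=int)]) \
        if len(anchor_bonds) else out.bonds
    return out


def _rotation_z_to(u: np.ndarray) -> np.ndarray:
    """Proper rotation matrix mapping the z axis onto unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    c = float(np.dot(z, u))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------

#: Atoms per interior residue; the N-terminus adds 2 H, the C-terminus 1 O.
RESIDUE_ATOM_COUNTS = {"GLY": 7, "SER": 11, "VAL": 16}

#: Kyte-Doolittle hydropathy scale (dimensionless; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


def lookup_hydropathy(residue: str) -> float:
    """Kyte-Doolittle hydropathy index of a residue (three-letter code)."""
    try:
        return KYTE_DOOLITTLE[residue.upper()]
    except KeyError:
        raise KeyError(f"no hydropathy entry for residue {residue!r}") from None


# Ideal backbone internal coordinates (nm / degrees).
_B_NCA, _B_CAC, _B_CN = 0.1458, 0.1525, 0.1329
_ANG_NCAC, _ANG_CACN, _ANG_CNCA = 111.0, 116.2, 121.7
_B_NH, _B_CO, _B_CH = 0.101, 0.1231, 0.109

# Idealized partial charges by atom name; per-residue sums are corrected on
# CA so each residue carries an exact integer formal charge.
_PEP_CHARGES = {
    "N": -0.50, "H": 0.30, "H1": 0.33, "H2": 0.33, "H3": 0.33,
    "CA": 0.14, "HA": 0.06, "HA1": 0.06, "HA2": 0.06,
    "C": 0.50, "O": -0.50, "OXT": -0.80,
    "CB": 0.145, "HB": 0.06, "HB1": 0.06, "HB2": 0.06,
    "OG": -0.683, "HG": 0.418,
    "CG1": -0.18, "CG2": -0.18,
    "HG11": 0.06, "HG12": 0.06, "HG13": 0.06,
    "HG21": 0.06, "HG22": 0.06, "HG23": 0.06,
}
_POLAR_H = {"H", "H1", "H2", "H3", "HG"}
_PEP_LJ = {  # element -> (sigma, epsilon); polar H get zeroed LJ
    "N": (0.325, 0.711), "C": (0.350, 0.276), "O": (0.296, 0.879),
    "H": (0.250, 0.1255),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom D from internal coordinates: |CD| = bond,
    angle(B, C, D) = ``angle`` and dihedral(A, B, C, D) = ``dihedral``
    (degrees, IUPAC sign convention)."""
    th = math.radians(angle)
    ph = -math.radians(dihedral)  # sign matches the IUPAC measurement convention
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(th),
                  bond * math.sin(th) * math.cos(ph),
                  bond * math.sin(th) * math.sin(ph)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _tetra_pair(center, n1, n2):
    """The two free substituent directions of a tetrahedral center with two
    known neighbours."""
    u1, u2 = _unit(n1 - center), _unit(n2 - center)
    b = -_unit(u1 + u2)
    p = _unit(np.cross(u1, u2))
    half = math.radians(109.47 / 2.0)
    return (_unit(b * math.cos(half) + p * math.sin(half)),
            _unit(b * math.cos(half) - p * math.sin(half)))


def _fourth_dir(center, n1, n2, n3):
    return -_unit(_unit(n1 - center) + _unit(n2 - center) + _unit(n3 - center))


def build_homopeptide(spec: PeptideSpec) -> MolecularSystem:
    """All-atom homopeptide at uniform backbone dihedrals.

    The backbone is propagated with ideal bond lengths and angles (trans
    peptide bond, omega = 180 deg); side chains and hydrogens are placed with
    tetrahedral geometry.  The amide hydrogen lies in the peptide plane
    opposite the preceding carbonyl, which reproduces helical hydrogen-bond
    geometry when helical (phi, psi) values are requested.
    """
    nres = spec.n_residues
    phi, psi = spec.conformation

    # backbone trace
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_NCA, 0.0, 0.0])]
    ang = math.radians(_ANG_NCAC)
    C = [CA[0] + _B_CAC * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, nres):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_CN, _ANG_CACN, psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_NCA, _ANG_CNCA, 180.0))
        C.append(place_atom(C[i - 1], N[i], CA[i], _B_CAC, _ANG_NCAC, phi))

    names: list[str] = []
    positions: list[np.ndarray] = []
    resids: list[int] = []
    bonds: list[tuple[int, int]] = []
    atom_index: dict[tuple[int, str], int] = {}

    def add(res: int, name: str, pos: np.ndarray,
            bond_to: tuple[int, str] | None) -> int:
        idx = len(names)
        names.append(name)
        positions.append(pos)
        resids.append(res)
        atom_index[(res, name)] = idx
        if bond_to is not None:
            bonds.append((atom_index[bond_to], idx))
        return idx

    for i in range(nres):
        add(i, "N", N[i], None if i == 0 else (i - 1, "C"))
        if i == 0:
            # protonated N-terminus: three tetrahedral hydrogens
            for j, dih in enumerate((60.0, 180.0, 300.0)):
                h = place_atom(C[0], CA[0], N[0], _B_NH, 109.47, dih)
                add(i, f"H{j + 1}", h, (i, "N"))
        else:
            hdir = -_unit(_unit(C[i - 1] - N[i]) + _unit(CA[i] - N[i]))
            add(i, "H", N[i] + _B_NH * hdir, (i, "N"))
        add(i, "CA", CA[i], (i, "N"))

        # side chain / alpha hydrogens
        d1, d2 = _tetra_pair(CA[i], N[i], C[i])
        if spec.residue == "GLY":
            add(i, "HA1", CA[i] + _B_CH * d1, (i, "CA"))
            add(i, "HA2", CA[i] + _B_CH * d2, (i, "CA"))
        else:
            CB = CA[i] + 0.153 * d1
            add(i, "CB", CB, (i, "CA"))
            add(i, "HA", CA[i] + _B_CH * _fourth_dir(CA[i], N[i], C[i], CB), (i, "CA"))
            if spec.residue == "SER":
                OG = place_atom(N[i], CA[i], CB, 0.141, 109.47, 180.0)
                add(i, "OG", OG, (i, "CB"))
                hb1, hb2 = _tetra_pair(CB, CA[i], OG)
                add(i, "HB1", CB + _B_CH * hb1, (i, "CB"))
                add(i, "HB2", CB + _B_CH * hb2, (i, "CB"))
                add(i, "HG", place_atom(CA[i], CB, OG, 0.0945, 108.5, 180.0), (i, "OG"))
            else:  # VAL
                CG1 = place_atom(N[i], CA[i], CB, 0.153, 109.47, 60.0)
                CG2 = place_atom(N[i], CA[i], CB, 0.153, 109.47, 300.0)
                add(i, "CG1", CG1, (i, "CB"))
                add(i, "CG2", CG2, (i, "CB"))
                add(i, "HB", CB + _B_CH * _fourth_dir(CB, CA[i], CG1, CG2), (i, "CB"))
                for gname, CG in (("HG1", CG1), ("HG2", CG2)):
                    for j, dih in enumerate((60.0, 180.0, 300.0)):
                        h = place_atom(CA[i], CB, CG, _B_CH, 109.47, dih)
                        add(i, f"{gname}{j + 1}", h, (i, "CG1" if CG is CG1 else "CG2"))

        add(i, "C", C[i], (i, "CA"))
        if i < nres - 1:
            odir = -_unit(_unit(CA[i] - C[i]) + _unit(N[i + 1] - C[i]))
            add(i, "O", C[i] + _B_CO * odir, (i, "C"))
        else:
            # carboxylate: two equivalent oxygens
            add(i, "O", place_atom(N[i], CA[i], C[i], 0.1249, 117.0, 90.0), (i, "C"))
            add(i, "OXT", place_atom(N[i], CA[i], C[i], 0.1249, 117.0, 270.0), (i, "C"))

    n_atoms = len(names)
    elements = np.array([nm[0] for nm in names], dtype=object)
    charges = np.array([_PEP_CHARGES[nm] for nm in names])
    # correct each residue's sum (on CA) to the exact formal charge
    resids_arr = np.array(resids)
    targets = np.zeros(nres)
    targets[0] += 1.0   # NH3+
    targets[-1] -= 1.0  # COO-
    for i in range(nres):
        mask = resids_arr == i
        delta = targets[i] - charges[mask].sum()
        charges[atom_index[(i, "CA")]] += delta

    sig = np.empty(n_atoms)
    eps = np.empty(n_atoms)
    for k, nm in enumerate(names):
        el = nm[0]
        if el == "H" and nm in _POLAR_H:
            sig[k], eps[k] = 0.0, 0.0
        else:
            sig[k], eps[k] = _PEP_LJ[el]
    return MolecularSystem(
        names=np.array(names, dtype=object),
        elements=elements,
        groups=np.full(n_atoms, GROUP_PEPTIDE, dtype=object),
        resids=resids_arr,
        resnames=np.full(n_atoms, spec.residue, dtype=object),
        positions=np.vstack(positions),
        charges=charges,
        sigmas=sig,
        epsilons=eps,
        masses=np.array([ELEMENT_MASSES[e] for e in elements]),
        box=max(6.0, 0.4 * nres),
        bonds=np.array(bonds, dtype=int),
    )


# ---------------------------------------------------------------------------
# Peptide placement
# ---------------------------------------------------------------------------

def place_peptide(system: MolecularSystem, peptide: MolecularSystem,
                  gap: float = 0.3) -> MolecularSystem:
    """Rigidly place the peptide next to the grafted layer.

    The approach is a rigid translation along the radial direction with the
    least layer occupancy (the azimuthal gap between grafted chains, found
    by minimising the layer's support function over 72 candidate azimuths),
    until the minimum inter-fragment atom distance falls in
    [gap, gap + 0.02] nm.  Among the 24 proper rotations of the octahedral
    group the orientation maximising the number of peptide atoms within
    0.6 nm of the layer is kept (greedy, deterministic).
    """
    if gap <= 0:
        raise InvalidSpecError("gap must be positive")
    layer = system.positions
    tree = cKDTree(layer)
    pep0 = peptide.positions - peptide.com()
    half_box = system.box / 2.0

    # least-occupied radial approach direction
    phis = np.arange(72) * (2.0 * math.pi / 72.0)
    support = np.array([
        (layer[:, 0] * math.cos(p) + layer[:, 1] * math.sin(p)).max()
        for p in phis])
    phi = float(phis[int(np.argmin(support))])
    u = np.array([math.cos(phi), math.sin(phi), 0.0])

    rots = Rotation.create_group("O")
    mats = rots.as_matrix()
    order = np.lexsort(mats.reshape(len(mats), -1).T[::-1])  # deterministic order
    best = None
    for mi in order:
        coords = pep0 @ mats[mi].T

        def min_dist(t: float) -> float:
            d, _ = tree.query(coords + t * u)
            return float(d.min())

        t_hi = float(np.abs(layer @ u).max() + np.abs(coords @ u).max()
                     + gap + 1.0)
        t_lo = 0.0
        if min_dist(t_hi) < gap:
            continue
        for _ in range(80):
            t_mid = 0.5 * (t_lo + t_hi)
            d = min_dist(t_mid)
            if gap <= d <= gap + 0.02:
                t_hi = t_mid
                break
            if d < gap:
                t_lo = t_mid
            else:
                t_hi = t_mid
        d = min_dist(t_hi)
        if not (gap <= d <= gap + 0.02):
            continue
        placed = coords + t_hi * u
        if np.abs(placed).max() > half_box:
            continue
        near = tree.query_ball_point(placed, 0.6)
        score = sum(1 for lst in near if lst)
        if best is None or score > best[0]:
            best = (score, placed)
    if best is None:
        raise PlacementError(
            f"no placement with gap {gap} nm fits inside the {system.box} nm box")
    pep = peptide.copy()
    pep.positions = best[1]
    return MolecularSystem.concat([system, pep], box=system.box)


# ---------------------------------------------------------------------------
# Solvent and ions
# ---------------------------------------------------------------------------

_TIP3_QO, _TIP3_QH = -0.834, 0.417
_TIP3_SIG_O, _TIP3_EPS_O = 0.315061, 0.6364
_WATER_OH, _WATER_ANG = 0.09572, 104.52
_NACL_MOLAR_MASS = 58.44

_ION_PARAMS = {
    "NA": (1.0, 0.333, 0.0116, ELEMENT_MASSES["NA"]),
    "CL": (-1.0, 0.4417, 0.4928, ELEMENT_MASSES["CL"]),
}


def _water_fragment(origin: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Positions of a rigid 3-site water (O, H1, H2) at the origin, rotated."""
    half = math.radians(_WATER_ANG / 2.0)
    local = np.array([
        [0.0, 0.0, 0.0],
        [_WATER_OH * math.sin(half), 0.0, _WATER_OH * math.cos(half)],
        [-_WATER_OH * math.sin(half), 0.0, _WATER_OH * math.cos(half)],
    ])
    return local @ rot.T + origin


def solvate(system: MolecularSystem | None, spec: SolventSpec,
            seed: int = 0) -> MolecularSystem:
    """Fill the box with rigid three-site waters on a jittered lattice.

    The number of candidate molecules equals round(density * volume); sites
    are drawn without replacement from a cubic lattice fine enough to hold
    them, jittered, then any molecule whose oxygen lies within
    ``exclusion_radius`` of a solute heavy atom is deleted.  ``system`` may
    be None to solvate an empty box.
    """
    rng = np.random.default_rng(seed)
    L = spec.box_edge
    n_target = int(round(spec.water_number_density * L ** 3))
    m = max(1, math.ceil(n_target ** (1.0 / 3.0)))
    spacing = L / m
    grid = (np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), axis=-1)
            .reshape(-1, 3) + 0.5) * spacing - L / 2.0
    chosen = rng.choice(len(grid), size=n_target, replace=False)
    sites = grid[chosen] + rng.uniform(-0.1 * spacing, 0.1 * spacing,
                                       size=(n_target, 3))

    if system is not None and system.n_atoms:
        if L < 2.0 * np.abs(system.positions).max():
            warnings.warn("box edge smaller than twice the solute extent",
                          stacklevel=2)
        heavy = system.positions[system.heavy()]
        tree = cKDTree(heavy)
        d, _ = tree.query(sites)
        sites = sites[d > spec.exclusion_radius]

    n_w = len(sites)
    pos = np.empty((3 * n_w, 3))
    rotmats = Rotation.random(n_w, random_state=np.random.RandomState(seed + 1)) \
        .as_matrix() if n_w else np.zeros((0, 3, 3))
    for i in range(n_w):
        pos[3 * i:3 * i + 3] = _water_fragment(sites[i], rotmats[i])

    bonds = np.column_stack([
        np.repeat(3 * np.arange(n_w), 2),
        (3 * np.arange(n_w)[:, None] + np.array([1, 2])).ravel(),
    ]) if n_w else np.zeros((0, 2), dtype=int)

    water = MolecularSystem(
        names=np.array(["OW", "HW1", "HW2"] * n_w, dtype=object),
        elements=np.array(["O", "H", "H"] * n_w, dtype=object),
        groups=np.full(3 * n_w, GROUP_WATER, dtype=object),
        resids=np.repeat(np.arange(n_w), 3),
        resnames=np.full(3 * n_w, "SOL", dtype=object),
        positions=pos,
        charges=np.tile([_TIP3_QO, _TIP3_QH, _TIP3_QH], n_w),
        sigmas=np.tile([_TIP3_SIG_O, 0.0, 0.0], n_w),
        epsilons=np.tile([_TIP3_EPS_O, 0.0, 0.0], n_w),
        masses=np.tile([ELEMENT_MASSES["O"], ELEMENT_MASSES["H"],
                        ELEMENT_MASSES["H"]], n_w),
        box=L,
        bonds=bonds,
    )
    if system is None or system.n_atoms == 0:
        return water
    return MolecularSystem.concat([system, water], box=L)


def add_ions(system: MolecularSystem, mass_conc: float = 9.0, seed: int = 0,
             water_number_density: float = 33.3) -> MolecularSystem:
    """Replace random waters by Na+ and Cl- at a NaCl mass concentration.

    The pair count is round(c_molar * N_A * V_water) with the water volume
    estimated as n_waters / bulk density; electroneutrality is preserved by
    construction (equal numbers of each ion replace neutral waters).
    """
    if mass_conc < 0:
        raise InvalidSpecError("mass_conc must be >= 0")
    if mass_conc == 0:
        return system.copy()
    water_res = np.unique(system.resids[system.groups == GROUP_WATER])
    n_waters = len(water_res)
    if n_waters == 0:
        raise CompositionError("cannot add ions: system contains no water")
    c_molar = mass_conc / _NACL_MOLAR_MASS
    v_water = n_waters / water_number_density
    n_pairs = int(round(c_molar * NA_PER_NM3 * v_water))
    if 2 * n_pairs > n_waters:
        raise CompositionError(
            f"need {2 * n_pairs} waters to replace, only {n_waters} present")
    if n_pairs == 0:
        return system.copy()

    rng = np.random.default_rng(seed)
    picked = rng.choice(water_res, size=2 * n_pairs, replace=False)
    ion_fragments = []
    for label, resname, resset in (("NA", "NA", picked[:n_pairs]),
                                   ("CL", "CL", picked[n_pairs:])):
        q, s, e, mass = _ION_PARAMS[label]
        for res in resset:
            o_idx = np.flatnonzero((system.resids == res)
                                   & (system.groups == GROUP_WATER))[0]
            ion_fragments.append(MolecularSystem(
                names=np.array([label], dtype=object),
                elements=np.array([label], dtype=object),
                groups=np.array([label], dtype=object),
                resids=np.zeros(1, dtype=int),
                resnames=np.array([resname], dtype=object),
                positions=system.positions[o_idx][None, :],
                charges=np.array([q]), sigmas=np.array([s]),
                epsilons=np.array([e]), masses=np.array([mass]),
                box=system.box,
            ))
    keep = ~np.isin(system.resids, picked) | (system.groups != GROUP_WATER)
    stripped = system.subset(np.flatnonzero(keep))
    return MolecularSystem.concat([stripped] + ion_fragments, box=system.box)
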