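"""Core containers shared by every stage of the pipeline.

Two objects travel through the whole package: :class:`MolecularSystem`, a
flat per-atom table (names, groups, positions, charges, LJ parameters,
masses) plus a cubic periodic box and a designated tube axis, and
:class:`Trajectory`, an ordered stack of coordinate frames sharing one
topology.

Unit conventions, used everywhere without exception: lengths in nm,
charges in elementary charge e, energies in kJ/mol, masses in amu,
angles in degrees, times in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

# Group labels partitioning atoms of a full system.
GROUP_CNT = "CNT"
GROUP_PEO = "PEO"
GROUP_PEPTIDE = "PEPTIDE"
GROUP_WATER = "WATER"
GROUP_NA = "NA"
GROUP_CL = "CL"

VALID_GROUPS = (GROUP_CNT, GROUP_PEO, GROUP_PEPTIDE, GROUP_WATER, GROUP_NA, GROUP_CL)

#: Standard atomic masses (amu) for the elements this package builds with.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "NA": 22.990,
    "CL": 35.453,
}

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458

#: kB*T at 298 K in kJ/mol.
KT_298 = 2.478957

#: Avogadro constant scaled so that mol/dm^3 * NA_PER_NM3 = particles/nm^3.
NA_PER_NM3 = 0.602214076


class NanobrushError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(NanobrushError, ValueError):
    """A build specification violates one of its invariants."""


class EmptyInputError(NanobrushError, ValueError):
    """An analysis was asked to operate on an empty selection/trajectory."""


@dataclass
class MolecularSystem:
    """Flat all-atom description of a (partial or complete) system.

    Attributes
    ----------
    names : array of str
        Atom names (e.g. ``CA``, ``OW``); not necessarily unique.
    elements : array of str
        Chemical element symbols, upper-case (``H``, ``C``, ``O``, ``NA`` ...).
    groups : array of str
        One of the labels in :data:`VALID_GROUPS`; partitions the atoms.
    resids : array of int
        0-based residue/molecule index, contiguous per molecule.
    resnames : array of str
        Residue names used for file output (``GLY``, ``PEO``, ``SOL`` ...).
    positions : (N, 3) float array, nm.
    charges : (N,) float array, e.
    sigmas, epsilons : (N,) float arrays
        Lennard-Jones parameters, nm and kJ/mol.
    masses : (N,) float array, amu.
    box : float
        Cubic box edge, nm; box is centered on the origin.
    axis : (3,) unit vector
        Nanotube axis; z by construction everywhere in this package.
    bonds : (B, 2) int array
        Covalent bond records (0-based atom indices). Used for donor-H
        pairing, anchors, and water rigidity; no bonded energies are ever
        evaluated.
    immobile : (N,) bool array
        True for atoms fixed in space (the tube carbons).
    """

    names: np.ndarray
    elements: np.ndarray
    groups: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    masses: np.ndarray
    box: float = 0.0
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    immobile: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if self.immobile is None:
            self.immobile = np.zeros(n, dtype=bool)
        else:
            self.immobile = np.asarray(self.immobile, dtype=bool)
        for arr, label in [
            (self.elements, "elements"), (self.groups, "groups"),
            (self.resids, "resids"), (self.resnames, "resnames"),
            (self.charges, "charges"), (self.sigmas, "sigmas"),
            (self.epsilons, "epsilons"), (self.masses, "masses"),
            (self.immobile, "immobile"),
        ]:
            if len(arr) != n:
                raise ValueError(f"field {label!r} has length {len(arr)}, expected {n}")

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def total_mass(self) -> float:
        return float(self.masses.sum())

    def indices(self, group: str) -> np.ndarray:
        """Indices of all atoms carrying the given group label."""
        return np.flatnonzero(self.groups == group)

    def heavy(self) -> np.ndarray:
        return np.flatnonzero(self.elements != "H")

    def com(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Mass-weighted center of mass of a subset (default: all atoms)."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        m = self.masses[idx]
        total = m.sum()
        if total <= 0:
            raise EmptyInputError("center of mass of a zero-mass selection")
        return (self.positions[idx] * m[:, None]).sum(axis=0) / total

    # -- structural edits ----------------------------------------------

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            names=self.names.copy(), elements=self.elements.copy(),
            groups=self.groups.copy(), resids=self.resids.copy(),
            resnames=self.resnames.copy(), positions=self.positions.copy(),
            charges=self.charges.copy(), sigmas=self.sigmas.copy(),
            epsilons=self.epsilons.copy(), masses=self.masses.copy(),
            box=self.box, axis=self.axis.copy(), bonds=self.bonds.copy(),
            immobile=self.immobile.copy(),
        )

    def translated(self, shift: np.ndarray) -> "MolecularSystem":
        out = self.copy()
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def subset(self, indices: Sequence[int]) -> "MolecularSystem":
        """New system containing only the given atoms; bonds are remapped
        and bonds crossing the subset boundary are dropped."""
        idx = np.asarray(indices, dtype=int)
        remap = -np.ones(self.n_atoms, dtype=int)
        remap[idx] = np.arange(len(idx))
        if len(self.bonds):
            keep = (remap[self.bonds[:, 0]] >= 0) & (remap[self.bonds[:, 1]] >= 0)
            bonds = remap[self.bonds[keep]]
        else:
            bonds = np.zeros((0, 2), dtype=int)
        return MolecularSystem(
            names=self.names[idx], elements=self.elements[idx],
            groups=self.groups[idx], resids=self.resids[idx],
            resnames=self.resnames[idx], positions=self.positions[idx],
            charges=self.charges[idx], sigmas=self.sigmas[idx],
            epsilons=self.epsilons[idx], masses=self.masses[idx],
            box=self.box, axis=self.axis.copy(), bonds=bonds,
            immobile=self.immobile[idx],
        )

    @staticmethod
    def concat(fragments: Iterable["MolecularSystem"],
               box: float | None = None) -> "MolecularSystem":
        """Merge fragments into one system, offsetting bond indices and
        residue indices so they stay unique."""
        frags = list(fragments)
        if not frags:
            raise ValueError("cannot concatenate zero fragments")
        offset = 0
        res_offset = 0
        cols: dict[str, list] = {k: [] for k in (
            "names", "elements", "groups", "resids", "resnames", "positions",
            "charges", "sigmas", "epsilons", "masses", "immobile")}
        bonds = []
        for f in frags:
            cols["names"].append(f.names)
            cols["elements"].append(f.elements)
            cols["groups"].append(f.groups)
            cols["resids"].append(f.resids + res_offset)
            cols["resnames"].append(f.resnames)
            cols["positions"].append(f.positions)
            cols["charges"].append(f.charges)
            cols["sigmas"].append(f.sigmas)
            cols["epsilons"].append(f.epsilons)
            cols["masses"].append(f.masses)
            cols["immobile"].append(f.immobile)
            if len(f.bonds):
                bonds.append(f.bonds + offset)
            offset += f.n_atoms
            res_offset += int(f.resids.max()) + 1 if f.n_atoms else 0
        return MolecularSystem(
            names=np.concatenate(cols["names"]),
            elements=np.concatenate(cols["elements"]),
            groups=np.concatenate(cols["groups"]),
            resids=np.concatenate(cols["resids"]),
            resnames=np.concatenate(cols["resnames"]),
            positions=np.vstack(cols["positions"]),
            charges=np.concatenate(cols["charges"]),
            sigmas=np.concatenate(cols["sigmas"]),
            epsilons=np.concatenate(cols["epsilons"]),
            masses=np.concatenate(cols["masses"]),
            box=box if box is not None else max(f.box for f in frags),
            axis=frags[0].axis.copy(),
            bonds=np.vstack(bonds) if bonds else np.zeros((0, 2), dtype=int),
            immobile=np.concatenate(cols["immobile"]),
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over one topology.

    ``ground_truth`` optionally carries the generating model of a synthetic
    ensemble so downstream estimators can be validated against it.
    """

    topology: MolecularSystem
    frames: np.ndarray          # (F, N, 3) nm
    times: np.ndarray           # (F,) ps, strictly increasing
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            self.frames = self.frames.reshape(-1, self.topology.n_atoms, 3)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frame/time count mismatch")
        if self.frames.shape[0] and self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_system(self, i: int) -> MolecularSystem:
        out = self.topology.copy()
        out.positions = self.frames[i].copy()
        return out


def minimum_image(delta: np.ndarray, box: float) -> np.ndarray:
    """Apply the cubic minimum-image convention to displacement vectors."""
    if box <= 0:
        return delta
    return delta - box * np.round(delta / box)
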