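"""Structure/trajectory file formats, atom selections, and parameter tables.

GRO (nm, fixed columns) is the canonical format; PDB (Angstrom) is supported
for interoperability, including multi-model files for trajectories.  Writers
are bit-stable for identical input.  Velocity columns in GRO files are
ignored on read and omitted on write.

Atom indices are 0-based internally and 1-based in every file written, as
both formats prescribe.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ELEMENT_MASSES, GROUP_CL, GROUP_CNT, GROUP_NA, GROUP_PEO, GROUP_PEPTIDE,
    GROUP_WATER, MolecularSystem, NanobrushError, Trajectory,
)

__all__ = [
    "read_structure", "write_structure", "read_trajectory", "write_trajectory",
    "select", "read_params", "apply_params",
    "ParseError", "SelectionSyntaxError", "SchemaError",
]


class ParseError(NanobrushError, ValueError):
    """Malformed fixed-width record; the message names the offending line."""


class SelectionSyntaxError(NanobrushError, ValueError):
    """Unparseable atom-selection expression."""


class SchemaError(NanobrushError, ValueError):
    """Parameter table missing required columns or empty."""


# residue name <-> group label conventions used by the builders
_RESNAME_TO_GROUP = {
    "CNT": GROUP_CNT, "PEO": GROUP_PEO, "SOL": GROUP_WATER,
    "NA": GROUP_NA, "CL": GROUP_CL,
}


def _group_for(resname: str) -> str:
    return _RESNAME_TO_GROUP.get(resname.upper(), GROUP_PEPTIDE)


def _element_for(name: str, resname: str) -> str:
    up = resname.upper()
    if up in ("NA", "CL"):
        return up
    return name.strip()[0].upper()


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _system_from_records(resids, resnames, names, positions, box):
    n = len(names)
    elements = np.array([_element_for(nm, rn) for nm, rn in zip(names, resnames)],
                        dtype=object)
    groups = np.array([_group_for(rn) for rn in resnames], dtype=object)
    masses = np.array([ELEMENT_MASSES.get(e, 0.0) for e in elements])
    return MolecularSystem(
        names=np.array(names, dtype=object),
        elements=elements, groups=groups,
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        positions=np.asarray(positions, dtype=float),
        charges=np.zeros(n), sigmas=np.zeros(n), epsilons=np.zeros(n),
        masses=masses, box=float(box),
    )


def _parse_gro_frame(lines, start):
    """Parse one GRO frame starting at ``lines[start]``; returns
    (system fields tuple, next line index)."""
    try:
        natoms = int(lines[start + 1].strip())
    except (IndexError, ValueError):
        raise ParseError(f"line {start + 2}: expected atom count") from None
    resids, resnames, names, pos = [], [], [], []
    for k in range(natoms):
        i = start + 2 + k
        if i >= len(lines):
            raise ParseError(f"line {i + 1}: file truncated inside atom records")
        ln = lines[i]
        if len(ln.rstrip("\n")) < 44:
            raise ParseError(f"line {i + 1}: truncated GRO atom record")
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            pos.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
        except ValueError:
            raise ParseError(f"line {i + 1}: malformed GRO atom record") from None
    bi = start + 2 + natoms
    if bi >= len(lines):
        raise ParseError(f"line {bi + 1}: missing box line")
    try:
        box = float(lines[bi].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"line {bi + 1}: malformed box line") from None
    return (resids, resnames, names, pos, box), bi + 1


def _read_gro(path: Path) -> MolecularSystem:
    lines = path.read_text().splitlines()
    (resids, resnames, names, pos, box), _ = _parse_gro_frame(lines, 0)
    # GRO resids are 1-based and wrap; renumber contiguously
    resids = _renumber(resids)
    sys = _system_from_records(resids, resnames, names, pos, box)
    sys.positions -= _gro_origin(box)
    return sys


def _gro_origin(box: float) -> np.ndarray:
    # GRO boxes conventionally span [0, L); internally the box is centered
    # on the origin.
    return np.array([box / 2.0] * 3)


def _renumber(resids) -> list[int]:
    out, cur, prev = [], -1, None
    for r in resids:
        if r != prev:
            cur += 1
            prev = r
        out.append(cur)
    return out


def _format_gro_frame(system: MolecularSystem, positions: np.ndarray,
                      title: str) -> str:
    lines = [title, f"{system.n_atoms:5d}"]
    shifted = positions + _gro_origin(system.box)
    for i in range(system.n_atoms):
        resid = (int(system.resids[i]) % 99999) + 1
        atomid = (i % 99999) + 1
        x, y, z = shifted[i]
        lines.append(
            f"{resid:5d}{str(system.resnames[i])[:5]:<5s}"
            f"{str(system.names[i])[:5]:>5s}{atomid:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{system.box:10.5f}{system.box:10.5f}{system.box:10.5f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _read_pdb(path: Path) -> MolecularSystem:
    lines = path.read_text().splitlines()
    resids, resnames, names, pos = [], [], [], []
    box = 0.0
    for i, ln in enumerate(lines):
        rec = ln[:6]
        if rec == "CRYST1":
            box = float(ln[6:15]) / 10.0
        elif rec in ("ATOM  ", "HETATM"):
            if len(ln) < 54:
                raise ParseError(f"line {i + 1}: truncated PDB atom record")
            try:
                names.append(ln[12:16].strip())
                resnames.append(ln[17:21].strip())
                resids.append(int(ln[22:26]))
                pos.append([float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0,
                            float(ln[46:54]) / 10.0])
            except ValueError:
                raise ParseError(f"line {i + 1}: malformed PDB atom record") from None
        elif rec == "ENDMDL":
            break
    if not names:
        raise ParseError("line 1: no atom records found")
    if box == 0.0:
        box = 2.0 * float(np.abs(pos).max()) if pos else 1.0
    sys = _system_from_records(_renumber(resids), resnames, names, pos, box)
    sys.positions -= _gro_origin(box)
    return sys


def _format_pdb_frame(system: MolecularSystem, positions: np.ndarray,
                      model: int | None) -> list[str]:
    lines = []
    if model is not None:
        lines.append(f"MODEL     {model:4d}")
    ang = (positions + _gro_origin(system.box)) * 10.0
    for i in range(system.n_atoms):
        name = str(system.names[i])[:4]
        # PDB name column: element-aligned for short names
        namefield = f" {name:<3s}" if len(name) < 4 else name
        el = str(system.elements[i])
        lines.append(
            f"ATOM  {(i % 99999) + 1:5d} {namefield} "
            f"{str(system.resnames[i])[:4]:<4s}A"
            f"{(int(system.resids[i]) % 9999) + 1:4d}    "
            f"{ang[i, 0]:8.3f}{ang[i, 1]:8.3f}{ang[i, 2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}")
    if model is not None:
        lines.append("ENDMDL")
    return lines


# ---------------------------------------------------------------------------
# Public structure / trajectory API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.upper()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gro", "pdb"):
        return suffix.upper()
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_structure(path, fmt: str | None = None) -> MolecularSystem:
    """Read a single-frame structure (GRO or PDB).  Positions are returned
    in nm with the box centered on the origin."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "GRO":
        return _read_gro(path)
    if fmt == "PDB":
        return _read_pdb(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_structure(system: MolecularSystem, path, fmt: str | None = None,
                    title: str = "nanobrush system") -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "GRO":
        path.write_text(_format_gro_frame(system, system.positions, title))
    elif fmt == "PDB":
        box_a = system.box * 10.0
        lines = [f"CRYST1{box_a:9.3f}{box_a:9.3f}{box_a:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"]
        lines += _format_pdb_frame(system, system.positions, None)
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a trajectory as concatenated GRO frames or a multi-model PDB."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "GRO":
        chunks = [
            _format_gro_frame(traj.topology, traj.frames[i],
                              f"nanobrush frame t= {traj.times[i]:.3f} ps")
            for i in range(traj.n_frames)
        ]
        path.write_text("".join(chunks))
    elif fmt == "PDB":
        box_a = traj.topology.box * 10.0
        lines = [f"CRYST1{box_a:9.3f}{box_a:9.3f}{box_a:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"]
        for i in range(traj.n_frames):
            lines += _format_pdb_frame(traj.topology, traj.frames[i], i + 1)
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_trajectory(path, fmt: str | None = None,
                    dt: float = 10.0) -> Trajectory:
    """Read concatenated GRO frames or a multi-model PDB into a Trajectory.

    Frame times are taken from GRO ``t=`` title annotations when present,
    otherwise spaced ``dt`` ps apart.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    frames, times = [], []
    topology = None
    if fmt == "GRO":
        lines = path.read_text().splitlines()
        i = 0
        while i < len(lines) and lines[i].strip():
            (resids, resnames, names, pos, box), i_next = _parse_gro_frame(lines, i)
            title = lines[i]
            if topology is None:
                topology = _system_from_records(_renumber(resids), resnames,
                                                names, pos, box)
                topology.positions -= _gro_origin(box)
            frames.append(np.asarray(pos) - _gro_origin(box))
            if "t=" in title:
                try:
                    times.append(float(title.split("t=")[1].split()[0]))
                except (ValueError, IndexError):
                    times.append(len(times) * dt)
            else:
                times.append(len(times) * dt)
            i = i_next
    elif fmt == "PDB":
        lines = path.read_text().splitlines()
        box = 0.0
        cur: list[list[float]] = []
        meta: list[tuple] = []
        for ii, ln in enumerate(lines):
            rec = ln[:6]
            if rec == "CRYST1":
                box = float(ln[6:15]) / 10.0
            elif rec in ("ATOM  ", "HETATM"):
                if len(ln) < 54:
                    raise ParseError(f"line {ii + 1}: truncated PDB atom record")
                cur.append([float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0,
                            float(ln[46:54]) / 10.0])
                if topology is None:
                    meta.append((int(ln[22:26]), ln[17:21].strip(),
                                 ln[12:16].strip()))
            elif rec == "ENDMDL":
                if topology is None:
                    resids = _renumber([m[0] for m in meta])
                    topology = _system_from_records(
                        resids, [m[1] for m in meta], [m[2] for m in meta],
                        cur, box)
                    topology.positions -= _gro_origin(box)
                frames.append(np.asarray(cur) - _gro_origin(box))
                times.append(len(times) * dt)
                cur = []
        if cur:  # single-model file without ENDMDL
            resids = _renumber([m[0] for m in meta])
            topology = _system_from_records(resids, [m[1] for m in meta],
                                            [m[2] for m in meta], cur, box)
            topology.positions -= _gro_origin(box)
            frames.append(np.asarray(cur) - _gro_origin(box))
            times.append(0.0)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if topology is None or not frames:
        raise ParseError("line 1: no frames found")
    return Trajectory(topology=topology, frames=np.stack(frames),
                      times=np.array(times))


# ---------------------------------------------------------------------------
# Atom selections
# ---------------------------------------------------------------------------
# Grammar:  expr   := term ('or' term)*
#           term   := factor ('and' factor)*
#           factor := 'not' factor | '(' expr ')' | primitive
#           primitive := 'group' NAME | 'element' NAME | 'name' NAME
#                      | 'resid' A[:B] | 'heavy' | 'all'

def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    def __init__(self, tokens: list[str], system: MolecularSystem):
        self.toks = tokens
        self.pos = 0
        self.sys = system

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression")
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionSyntaxError("missing closing parenthesis")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok = self.take()
        s = self.sys
        if tok == "heavy":
            return s.elements != "H"
        if tok == "all":
            return np.ones(s.n_atoms, dtype=bool)
        if tok in ("group", "element", "name"):
            arg = self.take()
            if arg is None:
                raise SelectionSyntaxError(f"{tok!r} needs an argument")
            if tok == "group":
                return s.groups == arg.upper()
            if tok == "element":
                return s.elements == arg.upper()
            return s.names == arg
        if tok == "resid":
            arg = self.take()
            if arg is None:
                raise SelectionSyntaxError("'resid' needs an argument")
            try:
                if ":" in arg:
                    lo, hi = (int(x) for x in arg.split(":"))
                else:
                    lo = hi = int(arg)
            except ValueError:
                raise SelectionSyntaxError(
                    f"bad resid range {arg!r}") from None
            return (s.resids >= lo) & (s.resids <= hi)
        raise SelectionSyntaxError(f"unknown token {tok!r}")


def select(system: MolecularSystem, expression: str) -> np.ndarray:
    """Evaluate a selection expression; returns a sorted, duplicate-free
    0-based index array."""
    mask = _SelParser(_tokenize(expression), system).parse()
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ["name", "mass", "charge", "sigma", "epsilon"]


def read_params(path) -> pd.DataFrame:
    """Read a per-atom parameter TSV with columns name/mass/charge/sigma/
    epsilon, indexed by atom name.  Duplicate names: last wins (warned)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"parameter table {path} is empty") from None
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter table missing columns: {missing}")
    if df.empty:
        raise SchemaError(f"parameter table {path} has no rows")
    dups = df["name"][df["name"].duplicated()].unique()
    if len(dups):
        warnings.warn(f"duplicate parameter rows for {list(dups)}; last wins",
                      stacklevel=2)
    return df.drop_duplicates("name", keep="last").set_index("name")


def apply_params(system: MolecularSystem, table: pd.DataFrame) -> MolecularSystem:
    """Assign mass/charge/LJ parameters to every atom by name.  All
    unresolved names are reported together."""
    unresolved = sorted({str(nm) for nm in system.names
                         if str(nm) not in table.index})
    if unresolved:
        raise SchemaError(f"unresolved atom names: {unresolved}")
    out = system.copy()
    rows = table.loc[[str(nm) for nm in system.names]]
    out.masses = rows["mass"].to_numpy(dtype=float)
    out.charges = rows["charge"].to_numpy(dtype=float)
    out.sigmas = rows["sigma"].to_numpy(dtype=float)
    out.epsilons = rows["epsilon"].to_numpy(dtype=float)
    return out


def write_params(system: MolecularSystem, path) -> None:
    """Write the per-atom-name parameter table of a system (one row per
    distinct atom name, last occurrence wins)."""
    df = pd.DataFrame({
        "name": [str(n) for n in system.names],
        "mass": system.masses, "charge": system.charges,
        "sigma": system.sigmas, "epsilon": system.epsilons,
    }).drop_duplicates("name", keep="last")
    df.to_csv(path, sep="\t", index=False)
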