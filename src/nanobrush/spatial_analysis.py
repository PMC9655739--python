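"""Geometric statistics around the nanotube axis.

Implements the time-averaged analyses used to characterise adsorption:

* cylindrical number-density profiles in concentric shells around the tube
  axis (shell thickness 0.1 nm, shell length 4.1 nm by default),
* radial distribution functions with the cubic minimum-image convention,
* the distance of a molecule's center of mass from the tube sidewall,
* radius of gyration and its Cartesian components (Rg^2 = Rgx^2+Rgy^2+Rgz^2),
* least-squares (Kabsch) superposition and RMSD time series,

        RMSD(t) = sqrt( (1/N) sum_i || r_i(t) - r_i(0) ||^2 )

  evaluated after optional rigid superposition onto the reference frame.

The tube axis is z throughout; cylindrical profiles deliberately do NOT use
the minimum image (the tube is unique in the box) while RDF distances do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EmptyInputError, MolecularSystem, NanobrushError, Trajectory, minimum_image

__all__ = [
    "CylindricalProfile", "RDFResult", "ConformationRecord", "RMSDSeries",
    "cylindrical_density", "rdf", "com_sidewall_distance", "gyration",
    "conformation_series", "superpose", "rmsd_series",
    "DegenerateSuperpositionError",
]


class DegenerateSuperpositionError(NanobrushError, ValueError):
    """Fewer than three atoms, or a collinear point set."""


@dataclass
class CylindricalProfile:
    """Shell-binned time-averaged number density around the tube axis.

    ``values[i] = counts[i] / shell_volume[i]`` with
    ``shell_volume[i] = pi (r_{i+1}^2 - r_i^2) * shell_length``; ``counts``
    are mean atoms per shell per frame, retained alongside the densities.
    """

    bin_edges: np.ndarray       # nm
    values: np.ndarray          # atoms nm^-3
    counts: np.ndarray          # mean atoms per shell
    shell_length: float         # nm
    selection: str = ""
    sidewall_radius: float | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        return np.pi * np.diff(self.bin_edges ** 2) * self.shell_length


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray     # mean pairs per bin per frame
    norm: np.ndarray            # ideal-gas pair count per bin


@dataclass
class ConformationRecord:
    """Per-frame COM--sidewall distance and gyration components with
    mean +/- sd summaries."""

    D: np.ndarray
    Rg: np.ndarray
    Rg_x: np.ndarray
    Rg_y: np.ndarray
    Rg_z: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for key in ("D", "Rg", "Rg_x", "Rg_y", "Rg_z"):
            v = getattr(self, key)
            out[key] = (float(v.mean()), float(v.std(ddof=0)))
        return out


@dataclass
class RMSDSeries:
    times: np.ndarray
    rmsd: np.ndarray
    reference_frame: int = 0
    superposed: bool = True


# ---------------------------------------------------------------------------

def _check_selection(traj: Trajectory, selection) -> np.ndarray:
    idx = np.asarray(selection, dtype=int)
    if traj.n_frames == 0:
        raise EmptyInputError("empty trajectory")
    if idx.size == 0:
        raise EmptyInputError("empty atom selection")
    return idx


def cylindrical_density(traj: Trajectory, selection,
                        bin_width: float = 0.1,
                        shell_length: float = 4.1,
                        r_max: float | None = None,
                        sidewall_radius: float | None = None,
                        selection_label: str = "") -> CylindricalProfile:
    """Time-averaged number density in cylindrical shells around the z axis.

    Atoms outside the axial slab |z| <= shell_length/2 (centered on the tube
    midpoint, the origin) are excluded from every shell.
    """
    idx = _check_selection(traj, selection)
    coords = traj.frames[:, idx, :]                    # (F, n, 3)
    if r_max is None:
        r_max = traj.topology.box * np.sqrt(2.0) / 2.0 if traj.topology.box > 0 \
            else float(np.hypot(coords[..., 0], coords[..., 1]).max()) + bin_width
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width

    rho = np.hypot(coords[..., 0], coords[..., 1])
    in_slab = np.abs(coords[..., 2]) <= shell_length / 2.0
    counts = np.zeros(n_bins)
    for f in range(traj.n_frames):
        h, _ = np.histogram(rho[f][in_slab[f]], bins=edges)
        counts += h
    counts /= traj.n_frames
    volumes = np.pi * np.diff(edges ** 2) * shell_length
    return CylindricalProfile(bin_edges=edges, values=counts / volumes,
                              counts=counts, shell_length=shell_length,
                              selection=selection_label,
                              sidewall_radius=sidewall_radius)


def rdf(traj: Trajectory, selection_a, selection_b,
        dr: float = 0.02, r_max: float | None = None) -> RDFResult:
    """Frame-averaged radial distribution function g(r) between two groups.

    Uses the cubic minimum-image convention.  For identical selections the
    self-RDF is computed over distinct pairs.  ``r_max`` must not exceed
    half the box edge.
    """
    ia = _check_selection(traj, selection_a)
    ib = _check_selection(traj, selection_b)
    box = traj.topology.box
    if r_max is None:
        r_max = box / 2.0
    if box > 0 and r_max > box / 2.0 + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half the box edge {box / 2}")
    same = len(ia) == len(ib) and np.array_equal(np.sort(ia), np.sort(ib))
    if same and len(ia) < 2:
        raise EmptyInputError("self-RDF needs at least two atoms")

    n_bins = int(np.round(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    hist = np.zeros(n_bins)
    for f in range(traj.n_frames):
        pa = traj.frames[f, ia]
        pb = traj.frames[f, ib]
        delta = pa[:, None, :] - pb[None, :, :]
        delta = minimum_image(delta, box)
        d = np.linalg.norm(delta, axis=-1)
        if same:
            iu = np.triu_indices(len(ia), k=1)
            d = d[iu]
        else:
            d = d.ravel()
        h, _ = np.histogram(d, bins=edges)
        hist += h
    hist /= traj.n_frames

    volume = box ** 3 if box > 0 else 4.0 / 3.0 * np.pi * r_max ** 3
    shell_vol = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    n_pairs = len(ia) * (len(ia) - 1) / 2.0 if same else len(ia) * len(ib)
    norm = n_pairs * shell_vol / volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, hist / norm, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(bin_centers=centers, g=g, pair_counts=hist, norm=norm)


def com_sidewall_distance(traj: Trajectory, selection,
                          cnt_radius: float) -> tuple[np.ndarray, float, float]:
    """Signed distance D(t) of the selection's center of mass from the tube
    sidewall: radial COM distance minus the tube radius.  Negative values
    (penetration past the wall) are reported as-is.

    Returns (per-frame D, mean, sd).
    """
    idx = _check_selection(traj, selection)
    m = traj.topology.masses[idx]
    if m.sum() <= 0:
        raise EmptyInputError("selection has zero total mass")
    w = m / m.sum()
    com = np.einsum("fni,n->fi", traj.frames[:, idx, :], w)
    d = np.hypot(com[:, 0], com[:, 1]) - cnt_radius
    return d, float(d.mean()), float(d.std(ddof=0))


def gyration(frame: np.ndarray, masses: np.ndarray | None = None,
             mass_weighted: bool = True) -> tuple[float, float, float, float]:
    """Radius of gyration and its Cartesian components of one coordinate set.

    Rg^2 = sum_i m_i |r_i - r_com|^2 / sum_i m_i and the per-axis analogue;
    the decomposition Rg^2 = Rgx^2 + Rgy^2 + Rgz^2 holds exactly.
    Returns (Rg, Rg_x, Rg_y, Rg_z).
    """
    coords = np.asarray(frame, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("empty selection")
    if masses is None or not mass_weighted:
        w = np.full(len(coords), 1.0 / len(coords))
    else:
        masses = np.asarray(masses, dtype=float)
        if masses.sum() <= 0:
            raise EmptyInputError("zero total mass")
        w = masses / masses.sum()
    com = (coords * w[:, None]).sum(axis=0)
    sq = ((coords - com) ** 2 * w[:, None]).sum(axis=0)   # per-axis
    rg2 = sq.sum()
    return (float(np.sqrt(rg2)), float(np.sqrt(sq[0])),
            float(np.sqrt(sq[1])), float(np.sqrt(sq[2])))


def conformation_series(traj: Trajectory, selection,
                        cnt_radius: float,
                        mass_weighted: bool = True) -> ConformationRecord:
    """Per-frame D, Rg and gyration components for a selection."""
    idx = _check_selection(traj, selection)
    masses = traj.topology.masses[idx]
    D, _, _ = com_sidewall_distance(traj, idx, cnt_radius)
    rg = np.empty(traj.n_frames)
    comps = np.empty((traj.n_frames, 3))
    for f in range(traj.n_frames):
        rg[f], comps[f, 0], comps[f, 1], comps[f, 2] = gyration(
            traj.frames[f, idx], masses, mass_weighted)
    return ConformationRecord(D=D, Rg=rg, Rg_x=comps[:, 0],
                              Rg_y=comps[:, 1], Rg_z=comps[:, 2])


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition (Kabsch).

    Returns (rotation, translation, rmsd_after) such that
    ``mobile @ rotation.T + translation`` best matches ``reference``.
    Reflections are rejected: the returned rotation is always proper
    (det = +1).  Degenerate inputs (< 3 atoms or a collinear set) raise.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError("coordinate shapes differ")
    if len(mob) < 3:
        raise DegenerateSuperpositionError("need at least 3 atoms")
    if weights is None:
        w = np.full(len(mob), 1.0 / len(mob))
    else:
        weights = np.asarray(weights, dtype=float)
        w = weights / weights.sum()
    cm = (mob * w[:, None]).sum(axis=0)
    cr = (ref * w[:, None]).sum(axis=0)
    x = mob - cm
    y = ref - cr
    # collinearity check on the weighted covariance of either set
    if np.linalg.matrix_rank(x.T @ (x * w[:, None]), tol=1e-12) < 2:
        raise DegenerateSuperpositionError("collinear point set")
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    moved = x @ rot.T + cr
    rmsd_after = float(np.sqrt((w * ((moved - ref) ** 2).sum(axis=1)).sum()))
    return rot, trans, rmsd_after


def rmsd_series(traj: Trajectory, selection, reference: int = 0,
                superpose_frames: bool = True,
                weights: np.ndarray | None = None) -> RMSDSeries:
    """Per-frame RMSD with respect to a reference frame.

    With superposition enabled (the default) each frame is first rigidly
    fitted onto the reference; the fit is unweighted unless weights are
    given, matching the plain per-atom RMSD definition.
    """
    idx = _check_selection(traj, selection)
    if not 0 <= reference < traj.n_frames:
        raise EmptyInputError(f"reference frame {reference} does not exist")
    ref = traj.frames[reference, idx]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.frames[f, idx]
        if superpose_frames:
            _, _, vals[f] = superpose(mob, ref, weights)
        else:
            vals[f] = float(np.sqrt(((mob - ref) ** 2).sum(axis=1).mean()))
    return RMSDSeries(times=traj.times.copy(), rmsd=vals,
                      reference_frame=reference, superposed=superpose_frames)
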