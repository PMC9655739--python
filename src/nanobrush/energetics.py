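"""MM-PBSA end-point binding free energies.

The binding free energy of a peptide (ligand) adsorbing on a grafted tube
(receptor) is assembled per frame from a single complex trajectory:

    dG_bind = dG_gas + dG_sol(complex) - dG_sol(receptor) - dG_sol(ligand)
    dG_gas  = dE_intra + dE_vdW + dE_coul          (dE_intra = 0, single
                                                    trajectory; the entropy
                                                    term is omitted)
    dG_sol  = G_polar + G_nonpolar

The polar term comes from a finite-difference linearized Poisson-Boltzmann
solver (successive over-relaxation on a uniform grid, dielectric boundary
from the union of atomic spheres, Debye-Hueckel Dirichlet boundary); the
nonpolar term is gamma * SASA with a Shrake-Rupley surface evaluated on a
deterministic Fibonacci sphere lattice.

Gas-phase pair sums carry no cutoff: the rescoring is an exact pair sum over
receptor-ligand pairs, independent of the switching scheme any MD engine
used to generate the configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import (
    EmptyInputError, F_COULOMB, KT_298, MolecularSystem, NA_PER_NM3,
    NanobrushError, Trajectory,
)

__all__ = [
    "PBConfig", "SASAConfig", "EnergyDecomposition",
    "lj_energy", "coulomb_energy", "solve_pb", "sasa",
    "binding_free_energy", "SingularityError", "pb_radii",
]


class SingularityError(NanobrushError, ValueError):
    """Coincident atoms in a pairwise energy sum."""


# ---------------------------------------------------------------------------
# Gas-phase pair terms
# ---------------------------------------------------------------------------

def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    r = cdist(pos_a, pos_b)
    if np.any(r < 1e-9):
        raise SingularityError("zero interatomic distance in pair sum")
    return r


def lj_energy(pos_a: np.ndarray, sig_a: np.ndarray, eps_a: np.ndarray,
              pos_b: np.ndarray, sig_b: np.ndarray, eps_b: np.ndarray) -> float:
    """Lennard-Jones cross energy between two groups, kJ/mol.

    Geometric-mean combination for both sigma and epsilon (OPLS convention),
    summed over all inter-group pairs with no cutoff.
    """
    r = _pair_distances(pos_a, pos_b)
    sig = np.sqrt(np.outer(sig_a, sig_b))
    eps = np.sqrt(np.outer(eps_a, eps_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
    return float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))


def coulomb_energy(pos_a: np.ndarray, q_a: np.ndarray,
                   pos_b: np.ndarray, q_b: np.ndarray) -> float:
    """Vacuum Coulomb cross energy, kJ/mol: f * sum q_i q_j / r_ij with
    f = 138.935458 kJ mol^-1 nm e^-2, no cutoff."""
    r = _pair_distances(pos_a, pos_b)
    return float(F_COULOMB * np.sum(np.outer(q_a, q_b) / r))


# ---------------------------------------------------------------------------
# Poisson-Boltzmann
# ---------------------------------------------------------------------------

@dataclass
class PBConfig:
    """Finite-difference linearized PB settings.

    grid_spacing : nm (default 0.05).
    eps_in / eps_out : solute and solvent dielectric constants (2 / 78.4).
    ionic_strength : mol/dm^3 of 1:1 salt in the solvent region (0 or 0.154).
    margin : nm of solvent buffer between solute spheres and the box faces.
    tol : relative SOR convergence tolerance.
    """

    grid_spacing: float = 0.05
    eps_in: float = 2.0
    eps_out: float = 78.4
    ionic_strength: float = 0.0
    margin: float = 1.0
    tol: float = 1e-6
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise ValueError("require eps_out >= eps_in >= 1")
        if self.grid_spacing <= 0 or self.margin <= 0:
            raise ValueError("grid_spacing and margin must be positive")


def pb_radii(sigmas: np.ndarray) -> np.ndarray:
    """Default PB/SASA atomic radii: the LJ minimum radius sigma/2 * 2^(1/6).
    Atoms with sigma = 0 (polar hydrogens) get a small 0.05 nm radius."""
    r = np.asarray(sigmas, dtype=float) / 2.0 * 2.0 ** (1.0 / 6.0)
    return np.where(r > 0, r, 0.05)


def _face_eps(dist_nodes: np.ndarray, axis: int, h: float,
              eps_in: float, eps_out: float) -> np.ndarray:
    """Harmonically averaged dielectric on the faces between nodes along one
    axis, from the signed distance to the solute surface at the two nodes.

    The inside fraction of each internode segment is estimated from the
    linear interpolant of the signed distance, which makes the boundary
    effectively smooth at the sub-grid level and gives monotone convergence
    under grid refinement.
    """
    d0 = np.moveaxis(dist_nodes, axis, 0)[:-1]
    d1 = np.moveaxis(dist_nodes, axis, 0)[1:]
    frac = np.clip(0.5 - (d0 + d1) / (2.0 * h), 0.0, 1.0)
    both_in = (d0 <= -h / 2) & (d1 <= -h / 2)
    both_out = (d0 >= h / 2) & (d1 >= h / 2)
    frac = np.where(both_in, 1.0, np.where(both_out, 0.0, frac))
    eps = 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)
    return np.moveaxis(eps, 0, axis)


def _solve_grid(rho: np.ndarray, ex, ey, ez, kappa2: np.ndarray,
                phi_bc: np.ndarray, h: float, tol: float,
                max_iter: int) -> np.ndarray:
    """Red-black SOR for  div(eps grad phi) - kappa2 phi = -4 pi f rho / h^3.

    ``phi_bc`` supplies Dirichlet values on the outermost node layer.
    """
    phi = phi_bc.copy()
    nx, ny, nz = phi.shape
    ii, jj, kk = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1),
                             np.arange(1, nz - 1), indexing="ij")
    red = ((ii + jj + kk) % 2 == 0)
    h2 = h * h
    src = 4.0 * math.pi * F_COULOMB * rho[1:-1, 1:-1, 1:-1] / (h2 * h)
    exl = ex[:-1, 1:-1, 1:-1]; exr = ex[1:, 1:-1, 1:-1]
    eyl = ey[1:-1, :-1, 1:-1]; eyr = ey[1:-1, 1:, 1:-1]
    ezl = ez[1:-1, 1:-1, :-1]; ezr = ez[1:-1, 1:-1, 1:]
    diag = (exl + exr + eyl + eyr + ezl + ezr) / h2 \
        + kappa2[1:-1, 1:-1, 1:-1]
    n_max = max(nx, ny, nz)
    omega = 2.0 / (1.0 + math.sin(math.pi / n_max))
    scale = None
    for it in range(max_iter):
        delta_max = 0.0
        for color in (red, ~red):
            numer = (exl * phi[:-2, 1:-1, 1:-1] + exr * phi[2:, 1:-1, 1:-1]
                     + eyl * phi[1:-1, :-2, 1:-1] + eyr * phi[1:-1, 2:, 1:-1]
                     + ezl * phi[1:-1, 1:-1, :-2] + ezr * phi[1:-1, 1:-1, 2:]
                     ) / h2 + src
            new = numer / diag
            interior = phi[1:-1, 1:-1, 1:-1]
            upd = interior + omega * (new - interior)
            delta_max = max(delta_max,
                            float(np.abs((upd - interior)[color]).max()))
            interior[color] = upd[color]
        if scale is None:
            scale = max(float(np.abs(phi).max()), 1e-30)
        if delta_max / max(float(np.abs(phi).max()), scale) < tol:
            break
    return phi


def solve_pb(positions: np.ndarray, charges: np.ndarray, radii: np.ndarray,
             config: PBConfig | None = None) -> float:
    """Polar (reaction-field) solvation energy G_pol in kJ/mol.

    Solves the linearized PB equation twice on the same grid and charge
    distribution -- once with the dielectric/salt map, once with a uniform
    eps_in reference -- and returns 0.5 * sum_i q_i (phi_solv - phi_ref) at
    the atom positions.  Grid self-energy cancels between the two solves.
    """
    cfg = config or PBConfig()
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    q = np.asarray(charges, dtype=float)
    rad = np.asarray(radii, dtype=float)
    if not np.any(q):
        return 0.0

    h = cfg.grid_spacing
    lo = (pos - rad[:, None]).min(axis=0) - cfg.margin
    hi = (pos + rad[:, None]).max(axis=0) + cfg.margin
    center = (lo + hi) / 2.0
    n_nodes = (np.ceil((hi - lo) / h).astype(int) // 2) * 2 + 1  # odd counts
    grids = [center[d] + (np.arange(n_nodes[d]) - n_nodes[d] // 2) * h
             for d in range(3)]
    shape = tuple(int(n) for n in n_nodes)

    # signed distance to the union of atom spheres at every node
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1)
    dist = np.full(shape, np.inf)
    for p, r in zip(pos, rad):
        d = np.linalg.norm(nodes - p, axis=-1) - r
        np.minimum(dist, d, out=dist)

    ex = _face_eps(dist, 0, h, cfg.eps_in, cfg.eps_out)
    ey = _face_eps(dist, 1, h, cfg.eps_in, cfg.eps_out)
    ez = _face_eps(dist, 2, h, cfg.eps_in, cfg.eps_out)

    # modified Helmholtz coefficient in the solvent region only
    kappa2 = np.zeros(shape)
    if cfg.ionic_strength > 0:
        c_num = cfg.ionic_strength * NA_PER_NM3          # nm^-3
        kbar2 = 8.0 * math.pi * F_COULOMB * c_num / KT_298
        kappa2[dist > 0] = kbar2
    kappa_d = math.sqrt(kappa2.max() / cfg.eps_out) if cfg.ionic_strength > 0 else 0.0

    # trilinear (cloud-in-cell) charge assignment
    rho = np.zeros(shape)
    frac = (pos - np.array([g[0] for g in grids])) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy,
                                base[:, 2] + dz), w * q)

    # Dirichlet boundaries: screened monopole (solvated) / bare Coulomb (ref)
    qtot = float(q.sum())
    qcenter = (pos * np.abs(q)[:, None]).sum(axis=0) / max(np.abs(q).sum(), 1e-30)
    r_nodes = np.linalg.norm(nodes - qcenter, axis=-1)
    r_nodes = np.maximum(r_nodes, h)
    bc_solv = np.zeros(shape)
    bc_ref = np.zeros(shape)
    edge = np.zeros(shape, dtype=bool)
    for d in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[d] = end
            edge[tuple(sl)] = True
    bc_solv[edge] = (F_COULOMB * qtot * np.exp(-kappa_d * r_nodes[edge])
                     / (cfg.eps_out * r_nodes[edge]))
    bc_ref[edge] = F_COULOMB * qtot / (cfg.eps_in * r_nodes[edge])

    phi_solv = _solve_grid(rho, ex, ey, ez, kappa2, bc_solv, h,
                           cfg.tol, cfg.max_iter)
    eps_unif = np.full_like(ex, cfg.eps_in), np.full_like(ey, cfg.eps_in), \
        np.full_like(ez, cfg.eps_in)
    phi_ref = _solve_grid(rho, *eps_unif, np.zeros(shape), bc_ref, h,
                          cfg.tol, cfg.max_iter)

    dphi = phi_solv - phi_ref
    # trilinear interpolation back to atom centers
    g_pol = 0.0
    for a in range(len(pos)):
        i, j, k = base[a]
        tx, ty, tz = t[a]
        val = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((tx if dx else 1 - tx) * (ty if dy else 1 - ty)
                         * (tz if dz else 1 - tz))
                    val += w * dphi[i + dx, j + dy, k + dz]
        g_pol += 0.5 * q[a] * val
    return float(g_pol)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@dataclass
class SASAConfig:
    """Shrake-Rupley quadrature settings.

    probe_radius : nm (default 0.14, water probe).
    n_sphere_points : deterministic Fibonacci-lattice points per atom (960).
    gamma : surface coefficient, kJ mol^-1 A^-2 (default 0.0227).
    offset : additive constant, kJ/mol.
    """

    probe_radius: float = 0.14
    n_sphere_points: int = 960
    gamma: float = 0.0227
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 92:
            raise ValueError("need at least 92 sphere points")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(positions: np.ndarray, radii: np.ndarray,
         config: SASAConfig | None = None) -> tuple[np.ndarray, float]:
    """Solvent-accessible surface area, per atom and total, nm^2.

    Each atom's accessible sphere (radius r_i + probe) is sampled on a
    deterministic Fibonacci lattice; a point is buried when it falls inside
    any neighbour's accessible sphere.
    """
    cfg = config or SASAConfig()
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    rad = np.asarray(radii, dtype=float)
    if np.any(rad < 0):
        raise ValueError("negative atomic radius")
    ext = rad + cfg.probe_radius
    unit = _fibonacci_sphere(cfg.n_sphere_points)
    tree = cKDTree(pos)
    areas = np.empty(len(pos))
    r_max = ext.max()
    for i in range(len(pos)):
        pts = pos[i] + ext[i] * unit
        nbrs = [j for j in tree.query_ball_point(pos[i], ext[i] + r_max)
                if j != i]
        if nbrs:
            d = cdist(pts, pos[nbrs])
            buried = (d < ext[nbrs][None, :] - 1e-12).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * ext[i] ** 2
    return areas, float(areas.sum())


def nonpolar_energy(total_area_nm2: float, config: SASAConfig | None = None) -> float:
    """G_nonpol = gamma * SASA + offset, with gamma per Angstrom^2."""
    cfg = config or SASAConfig()
    return cfg.gamma * total_area_nm2 * 100.0 + cfg.offset


# ---------------------------------------------------------------------------
# MM-PBSA assembly
# ---------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    """Per-frame MM-PBSA terms (kJ/mol) and their window averages.

    ``E_intra`` is identically zero under the single-trajectory scheme and
    carried explicitly so the gas-phase decomposition keeps its full shape.
    """

    frames: np.ndarray
    E_intra: np.ndarray
    E_vdW: np.ndarray
    E_coul: np.ndarray
    dG_pol: np.ndarray
    dG_nonpol: np.ndarray

    @property
    def dG_gas(self) -> np.ndarray:
        return self.E_intra + self.E_vdW + self.E_coul

    @property
    def dG_sol(self) -> np.ndarray:
        return self.dG_pol + self.dG_nonpol

    @property
    def dG_bind(self) -> np.ndarray:
        return self.dG_gas + self.dG_sol

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for key in ("E_intra", "E_vdW", "E_coul", "dG_pol", "dG_nonpol",
                    "dG_gas", "dG_sol", "dG_bind"):
            v = getattr(self, key)
            out[key] = (float(np.mean(v)), float(np.std(v, ddof=0)))
        return out


def binding_free_energy(traj: Trajectory, receptor, ligand,
                        pb: PBConfig | None = None,
                        sasa_cfg: SASAConfig | None = None,
                        frame_window: slice | None = None,
                        radii: np.ndarray | None = None) -> EnergyDecomposition:
    """Single-trajectory MM-PBSA over a frame window.

    Receptor and ligand coordinates are extracted from each complex frame,
    so intramolecular terms cancel exactly (dE_intra = 0).  The default
    window is the final third of the trajectory, emulating production-tail
    averaging.
    """
    rec = np.asarray(receptor, dtype=int)
    lig = np.asarray(ligand, dtype=int)
    if np.intersect1d(rec, lig).size:
        raise ValueError("receptor and ligand selections overlap")
    if traj.n_frames == 0:
        raise EmptyInputError("empty trajectory")
    if frame_window is None:
        frame_window = slice(2 * traj.n_frames // 3, traj.n_frames)
    frame_ids = np.arange(traj.n_frames)[frame_window]
    if frame_ids.size == 0:
        raise EmptyInputError("empty frame window")

    top = traj.topology
    all_radii = pb_radii(top.sigmas) if radii is None else np.asarray(radii)
    sasa_cfg = sasa_cfg or SASAConfig()
    pb = pb or PBConfig()

    n = frame_ids.size
    evdw = np.empty(n)
    ecoul = np.empty(n)
    dgpol = np.empty(n)
    dgnp = np.empty(n)
    for k, f in enumerate(frame_ids):
        pr = traj.frames[f, rec]
        pl = traj.frames[f, lig]
        evdw[k] = lj_energy(pr, top.sigmas[rec], top.epsilons[rec],
                            pl, top.sigmas[lig], top.epsilons[lig])
        ecoul[k] = coulomb_energy(pr, top.charges[rec], pl, top.charges[lig])

        pc = np.vstack([pr, pl])
        qc = np.concatenate([top.charges[rec], top.charges[lig]])
        rc = np.concatenate([all_radii[rec], all_radii[lig]])
        g_pc = solve_pb(pc, qc, rc, pb)
        g_p = solve_pb(pr, top.charges[rec], all_radii[rec], pb)
        g_l = solve_pb(pl, top.charges[lig], all_radii[lig], pb)
        dgpol[k] = g_pc - g_p - g_l

        _, a_pc = sasa(pc, rc, sasa_cfg)
        _, a_p = sasa(pr, all_radii[rec], sasa_cfg)
        _, a_l = sasa(pl, all_radii[lig], sasa_cfg)
        dgnp[k] = (nonpolar_energy(a_pc, sasa_cfg)
                   - nonpolar_energy(a_p, sasa_cfg)
                   - nonpolar_energy(a_l, sasa_cfg))
    return EnergyDecomposition(frames=frame_ids, E_intra=np.zeros(n),
                               E_vdW=evdw, E_coul=ecoul, dG_pol=dgpol,
                               dG_nonpol=dgnp)
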