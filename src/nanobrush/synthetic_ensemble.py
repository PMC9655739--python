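"""Synthetic configuration ensembles with known statistical ground truth.

Instead of molecular dynamics, trajectories are generated directly from a
stated statistical model so every estimator downstream can be validated
against the generating parameters:

* the peptide is rigid-placed per frame with its center of mass at a radial
  distance drawn from a normal distribution truncated at the tube sidewall
  (reject-and-resample keeps configurations physical), uniform axial and
  angular position, plus optional per-atom Gaussian jitter;
* water, when present, is redrawn each frame from an inhomogeneous density
  field bulk * g(rho) around the tube axis (frames are independent -- no
  dynamics is implied; frame times are labels only);
* minimal donor-H-acceptor triple systems realise a prescribed hydrogen-bond
  occupancy p per pair per frame;
* an ideal-gas generator provides the null model for density and RDF
  estimators.

Everything is bit-reproducible under an explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    ELEMENT_MASSES, GROUP_CNT, GROUP_PEPTIDE, GROUP_WATER, InvalidSpecError,
    MolecularSystem, Trajectory,
)

__all__ = ["EnsembleModel", "generate_ensemble", "generate_hbond_ensemble",
           "ideal_gas_frames", "FRAME_SPACING_PS"]

#: Default frame spacing label, ps (conformation-sampling interval parity).
FRAME_SPACING_PS = 10.0


@dataclass
class EnsembleModel:
    """Statistical ground truth of a generated ensemble.

    com_radial_mean / com_radial_sd : rho_0 and sigma_rho of the peptide COM
        radial placement (nm); truncated below at the sidewall radius.
    internal_jitter_sd : per-atom isotropic Gaussian jitter (nm).
    hbond_occupancy : probability p that a designated donor-acceptor pair is
        inside the H-bond criterion in a frame.
    water_profile : dimensionless multiplier g(rho) on the bulk density.
    """

    com_radial_mean: float = 1.0
    com_radial_sd: float = 0.1
    axial_uniform: bool = True
    internal_jitter_sd: float = 0.0
    hbond_occupancy: float = 0.0
    water_profile: Callable[[np.ndarray], np.ndarray] | None = None
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hbond_occupancy <= 1.0:
            raise InvalidSpecError("hbond_occupancy must be in [0, 1]")
        if self.com_radial_sd < 0:
            raise InvalidSpecError("com_radial_sd must be >= 0")
        if self.internal_jitter_sd < 0:
            raise InvalidSpecError("internal_jitter_sd must be >= 0")
        if self.n_frames < 0:
            raise InvalidSpecError("n_frames must be >= 0")


def _truncated_normal_radius(rng, mean, sd, lower) -> float:
    if sd == 0.0:
        if mean < lower:
            raise InvalidSpecError("radial mean below the sidewall radius")
        return mean
    for _ in range(10000):
        r = rng.normal(mean, sd)
        if r >= lower:
            return float(r)
    raise InvalidSpecError("truncated-normal sampling failed: mean far below wall")


def generate_ensemble(system: MolecularSystem, model: EnsembleModel) -> Trajectory:
    """Generate a rigid-placement ensemble of a peptide around a tube.

    Per frame the peptide is translated so its COM sits at radius ~
    TruncNormal(rho_0, sigma_rho, lower = sidewall radius), uniform angle and
    uniform axial position within the tube span, then per-atom Gaussian
    jitter is added.  Water molecules (if any) are redrawn rigidly from the
    inhomogeneous field bulk * g(rho) by thinning.  All other atoms keep
    their topology coordinates.
    """
    pep = system.indices(GROUP_PEPTIDE)
    cnt = system.indices(GROUP_CNT)
    if pep.size == 0 or cnt.size == 0:
        raise InvalidSpecError("system must contain PEPTIDE and CNT groups")
    wall_r = float(np.hypot(system.positions[cnt, 0],
                            system.positions[cnt, 1]).mean())
    if model.com_radial_mean < wall_r:
        raise InvalidSpecError(
            f"com_radial_mean {model.com_radial_mean} below sidewall radius "
            f"{wall_r:.4f}")
    rng = np.random.default_rng(model.seed)
    z_span = float(system.positions[cnt, 2].max() - system.positions[cnt, 2].min())

    wat_o = np.flatnonzero((system.groups == GROUP_WATER)
                           & (system.names == "OW"))
    wat_res = system.resids[wat_o]
    box = system.box

    pep_local = system.positions[pep] - system.com(pep)
    frames = np.tile(system.positions, (model.n_frames, 1, 1))
    for f in range(model.n_frames):
        rho = _truncated_normal_radius(rng, model.com_radial_mean,
                                       model.com_radial_sd, wall_r)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        z = rng.uniform(-z_span / 2.0, z_span / 2.0) if model.axial_uniform else 0.0
        com = np.array([rho * math.cos(theta), rho * math.sin(theta), z])
        coords = pep_local + com
        if model.internal_jitter_sd > 0:
            coords = coords + rng.normal(0.0, model.internal_jitter_sd,
                                         coords.shape)
        frames[f, pep] = coords

        if wat_o.size and model.water_profile is not None:
            frames[f] = _resample_water(frames[f], system, wat_o, wat_res,
                                        model.water_profile, box, rng)
        elif wat_o.size:
            frames[f] = _resample_water(frames[f], system, wat_o, wat_res,
                                        lambda r: np.ones_like(r), box, rng)
    times = np.arange(model.n_frames) * FRAME_SPACING_PS
    return Trajectory(topology=system, frames=frames, times=times,
                      ground_truth={"model": model, "sidewall_radius": wall_r})


def _resample_water(frame, system, wat_o, wat_res, g, box, rng):
    """Redraw water oxygen positions from the field bulk*g(rho) by rejection
    (thinning); hydrogens follow rigidly."""
    n = len(wat_o)
    # estimate g_max on a radial grid for the acceptance bound
    rr = np.linspace(0.0, box * math.sqrt(2) / 2.0, 256)
    g_max = float(np.max(g(rr))) * 1.05 + 1e-12
    accepted = np.empty((0, 3))
    while len(accepted) < n:
        m = max(4 * (n - len(accepted)), 64)
        cand = rng.uniform(-box / 2.0, box / 2.0, size=(m, 3))
        rho = np.hypot(cand[:, 0], cand[:, 1])
        keep = rng.uniform(0.0, g_max, size=m) < np.asarray(g(rho))
        accepted = np.vstack([accepted, cand[keep]])
    new_o = accepted[:n]
    for k, oi in enumerate(wat_o):
        mol = np.flatnonzero((system.resids == wat_res[k])
                             & (system.groups == GROUP_WATER))
        offset = new_o[k] - system.positions[oi]
        frame[mol] = system.positions[mol] + offset
    return frame


# ---------------------------------------------------------------------------

def generate_hbond_ensemble(n_pairs: int, p: float, n_frames: int,
                            seed: int = 0) -> Trajectory:
    """Minimal donor-H-acceptor triples realising occupancy p.

    Each pair, in each frame independently, is placed inside the geometric
    criterion with probability p (collinear O-H...O at d_DA = 0.29 nm) and
    outside it otherwise (d_DA = 0.45 nm).  The expected detected count per
    frame is p * n_pairs.  Triples are spaced far apart so no cross-pair
    bond can occur.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidSpecError("occupancy p must be in [0, 1]")
    spacing = 2.0
    side = int(math.ceil(n_pairs ** (1.0 / 3.0)))
    origins = np.array([[i, j, k] for i in range(side) for j in range(side)
                        for k in range(side)], dtype=float)[:n_pairs] * spacing
    origins -= origins.mean(axis=0)

    names, elements, pos0, bonds = [], [], [], []
    for k, o in enumerate(origins):
        d_idx = 3 * k
        names += ["OD", "HD", "OA"]
        elements += ["O", "H", "O"]
        pos0 += [o, o + [0.0957, 0.0, 0.0], o + [0.29, 0.0, 0.0]]
        bonds.append((d_idx, d_idx + 1))
    n_atoms = 3 * n_pairs
    top = MolecularSystem(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        groups=np.full(n_atoms, GROUP_PEPTIDE, dtype=object),
        resids=np.repeat(np.arange(n_pairs), 3),
        resnames=np.full(n_atoms, "HBX", dtype=object),
        positions=np.array(pos0),
        charges=np.zeros(n_atoms), sigmas=np.zeros(n_atoms),
        epsilons=np.zeros(n_atoms),
        masses=np.array([ELEMENT_MASSES[e] for e in elements]),
        box=max(2.0 * spacing * side, 8.0),
        bonds=np.array(bonds, dtype=int),
    )
    rng = np.random.default_rng(seed)
    frames = np.tile(top.positions, (n_frames, 1, 1))
    for f in range(n_frames):
        bound = rng.uniform(size=n_pairs) < p
        for k in range(n_pairs):
            a_idx = 3 * k + 2
            d = 0.29 if bound[k] else 0.45
            frames[f, a_idx] = origins[k] + [d, 0.0, 0.0]
    times = np.arange(n_frames) * FRAME_SPACING_PS
    return Trajectory(topology=top, frames=frames, times=times,
                      ground_truth={"n_pairs": n_pairs, "p": p, "seed": seed})


def ideal_gas_frames(box: float, n_atoms: int, n_frames: int,
                     seed: int = 0) -> Trajectory:
    """I.i.d. uniform positions in a cubic box each frame: the null model for
    density-profile and RDF estimators."""
    if n_atoms < 2:
        raise InvalidSpecError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    top = MolecularSystem(
        names=np.array([f"AR{i}" for i in range(n_atoms)], dtype=object),
        elements=np.full(n_atoms, "C", dtype=object),
        groups=np.full(n_atoms, GROUP_PEPTIDE, dtype=object),
        resids=np.arange(n_atoms),
        resnames=np.full(n_atoms, "GAS", dtype=object),
        positions=np.zeros((n_atoms, 3)),
        charges=np.zeros(n_atoms), sigmas=np.zeros(n_atoms),
        epsilons=np.zeros(n_atoms),
        masses=np.full(n_atoms, 12.011),
        box=float(box),
    )
    frames = rng.uniform(-box / 2.0, box / 2.0, size=(n_frames, n_atoms, 3))
    if n_frames == 0:
        frames = np.zeros((0, n_atoms, 3))
    top.positions = frames[0].copy() if n_frames else top.positions
    times = np.arange(n_frames) * FRAME_SPACING_PS
    return Trajectory(topology=top, frames=frames, times=times,
                      ground_truth={"density": n_atoms / box ** 3})
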