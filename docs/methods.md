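# Methods

This note documents the models, parameters, and numerical choices behind
`nanobrush`, and states precisely what the synthetic-ensemble validation
does and does not establish.

Units throughout: nm, kJ·mol⁻¹, elementary charge e, amu, degrees, ps.

## System construction

**Nanotube.** A zigzag (n, 0) single-walled tube is obtained by rolling an
ideal graphene sheet with lattice constant a = 0.246 nm (C–C bond
a/√3 = 0.142 nm). The diameter is d = (a/π)√(n² + nm + m²); every carbon
lies exactly on the cylinder of radius d/2, the axis is z, and the tube is
uncapped and centered on the origin. The translational period of a zigzag
tube is √3·a ≈ 0.426 nm with 4n atoms per period; a requested length is
truncated to complete periods. Tube carbons carry zero charge, a single
aromatic-carbon LJ type (σ = 0.355 nm, ε = 0.293 kJ/mol), and are flagged
immobile — they participate only in nonbonded interactions.

*Report-parity convention.* The printed setup numbers for the (10,0) tube —
diameter 0.8 nm, sidewall area 10.3 nm², grafting densities 0.388/0.776/
1.553 nm⁻² for 4/8/16 chains — follow from the one-decimal *nominal*
diameter (area = π·0.8·4.1). Both the exact (0.7830 nm, 10.09 nm²) and
nominal values are computed; the nominal one is used for reported σ so all
five setup numbers are reproduced simultaneously.

**PEO brush.** Chains are (–CH₂–CH₂–O–)_N with N = 18 and a terminal
methoxy group (heavy atoms 3N + 1), built as a stretched 7/2 helix: two
turns per seven monomers, default rise 0.28 nm/monomer (crystalline-PEO
fiber repeat), helix radius 0.15 nm. Partial charges are idealized
(ether O −0.4, adjacent C +0.2, H 0) and sum to zero per chain. Anchoring
is a bond record between the first methylene carbon and a sidewall carbon;
no bonded energies are ever evaluated downstream.

*Grafting pattern.* "Evenly distributed" is made deterministic as follows:
among all divisor factorizations r rings × k angular slots = N_chains that
fit the tube, the pattern whose ideal sites maximize the minimum pairwise
geodesic (cylinder-surface) separation is chosen; adjacent rings are
rotated by half an angular spacing, and ideal sites snap to the nearest
unused sidewall carbon. A naive smallest-ring-count rule was rejected
because for 16 chains it packs 8 anchors onto one 10-carbon ring, creating
0.246 nm adjacencies that even random placements beat. An explicit ring
count can override the rule (e.g. 2 rings × 4 for 8 chains).

**Homopeptides.** Polyglycine, polyserine, and polyvaline (24 residues by
default) are built residue-by-residue from ideal internal coordinates
(N–CA 0.1458, CA–C 0.1525, C–N 0.1329 nm; trans peptide bond ω = 180°) at a
uniform backbone (φ, ψ), default extended β (−135°, 135°). The amide
hydrogen is placed in the peptide plane opposite the preceding carbonyl,
which makes ideal α-helical (−57°, −47°) and 3₁₀ (−49°, −26°) inputs
reproduce their canonical i→i+4 / i→i+3 hydrogen-bond patterns without
tuning. The N-terminus is protonated (NH₃⁺, +1), the C-terminus dissociated
(COO⁻, −1); partial charges are idealized per atom name with a per-residue
correction on CA so each residue carries an exact integer formal charge and
the chain is an exact zwitterion.

**Placement.** The peptide approaches the grafted layer as a rigid body
along the radial direction where the layer's support function is smallest —
the azimuthal gap between grafted chains. (A fixed approach direction can
run into a stretched chain tip ~5.6 nm from the axis and then nothing fits
an 11–12 nm box; the gap-directed approach reproduces the intended
"maximal close contacts" starting geometry.) The translation is bisected
until the minimum inter-fragment distance lies in [gap, gap + 0.02] nm
(default gap 0.3 nm); among the 24 proper rotations of the octahedral group
the orientation with the most peptide atoms within 0.6 nm of the layer wins,
ties resolved deterministically.

**Solvent and ions.** Water is a rigid 3-site model (O–H 0.09572 nm,
104.52°, q_O = −0.834) placed on a jittered cubic lattice; the candidate
count equals round(ρ·V) exactly (bulk ρ = 33.3 nm⁻³), and any molecule
whose oxygen lies within the exclusion radius of a solute heavy atom is
deleted. The exclusion radius defaults to 0.26 nm (≈ the C–O LJ contact
distance); with it, the pristine-tube 6 nm box retains 7012 waters —
consistent with the reference count of 7010 without any tuning. NaCl at
mass concentration c (9.0 g·dm⁻³ ≡ 0.154 mol·dm⁻³, molar mass 58.44)
replaces round(c·N_A·V_water) water pairs by Na⁺/Cl⁻ uniformly at random
under the seed, preserving electroneutrality exactly.

## Synthetic ensembles

The generator emulates the *statistical* structure of adsorption
trajectories, not their dynamics: per frame the peptide is rigid-placed
with COM radius ~ Normal(ρ₀, σ_ρ) truncated at the sidewall (rejection
sampling), uniform angle and axial position, plus optional per-atom
Gaussian jitter; water is redrawn independently each frame from the field
bulk·g(ρ) by thinning. Because frames share one topology the water count is
fixed, so the field is the count-conditioned (multinomial) version of the
stated inhomogeneous Poisson field — flat-profile and Poisson-band
properties are unaffected. Frame times are 10 ps labels for report parity
only.

What a green validation establishes: the estimators (cylindrical density,
D, R_g, H-bond counts, RDF) are unbiased and correctly normalized, since
they recover ρ₀, g(ρ), and the H-bond occupancy p within their sampling
bands at 500 frames. What it does not establish: anything about real
adsorption physics — time correlations, realistic conformational
distributions, brush deformation, or solvent structure. Trajectory-scale
published observables (wall distances and gyration radii per system,
per-system H-bond counts, absolute binding free energies) require tens of
ns of atomistic MD with up to ~56,000 waters plus unpublished PB parameters
and are deliberately out of scope.

## Analysis conventions

* Cylindrical profiles: shells of 0.1 nm around the z axis, shell length
  4.1 nm centered on the tube midplane; atoms outside the axial slab are
  excluded; both raw mean counts per shell and densities (counts/shell
  volume) are emitted because the published ordinate convention is
  ambiguous. No minimum image — the tube is unique in the box.
* RDFs use the cubic minimum-image convention; r_max ≤ box/2 enforced.
* D is *signed* (COM radius minus wall radius); penetration would be
  reported negative, never clipped.
* PEO analyses conventionally use heavy atoms only; peptide analyses all
  atoms (selection strings `group PEO and heavy`, `group PEPTIDE`).
* Superposition is Kabsch with reflection rejection (det = +1 enforced);
  RMSD series default to unweighted fits, matching the plain RMSD
  definition; mass-weighted fits are available.
* Hydrogen bonds: d(D···A) ≤ 0.35 nm and ≤ 30° deviation from linearity.
  The deviation is the angle between D→H and D→A by default ("donor"
  convention, the common MD-package choice); the 180° − ∠(D–H···A)
  convention is selectable since the two differ at the margins. Pairs
  within two covalent bonds are excluded. Donors are N–H and O–H pairs
  derived from the bond table; acceptors are all oxygens (PEO ether oxygens
  accept but never donate).
* Secondary structure is a pattern-based stand-in for energy/propensity
  assigners: two consecutive i→i+4 backbone bonds → α-helix; two
  consecutive i→i+3 → 3₁₀; long-range bridges, adjacent → β-sheet, single →
  isolated bridge; unextended i→i+3/4/5 bonds → turn; else coil. Priority
  H > G > E > B > T > C, one label per residue.
* Na⁺ bridge cutoff 0.32 nm (typical first minimum of Na⁺–O RDFs),
  configurable.

## MM-PBSA

Single-trajectory scheme: receptor (tube + brush) and ligand (peptide)
coordinates are extracted from each complex frame, so intramolecular terms
cancel; ΔE_intra is carried as an explicit zero to keep the full gas-phase
decomposition shape. The configurational-entropy term is omitted — it is
small, expensive, and does not improve relative predictions. Averages are
taken over the final third of frames by default (production-tail
averaging). Gas-phase LJ and Coulomb sums run over all receptor–ligand
pairs with no cutoff (OPLS geometric-mean combination for σ and ε;
f = 138.935458 kJ·mol⁻¹·nm·e⁻²).

**Poisson–Boltzmann.** The linearized equation ∇·(ε∇φ) − κ̄²φ = −4πf·ρ is
solved on a uniform grid (default spacing 0.05 nm, solute + 1.0 nm margin)
by red–black successive over-relaxation with ω = 2/(1 + sin(π/n)), to a
relative update tolerance of 10⁻⁶. The dielectric is ε_in (default 2)
inside the union of atomic spheres (radius σ/2·2^(1/6), i.e. the LJ
minimum radius) and ε_out = 78.4 outside; face dielectrics are harmonic
averages weighted by the inside fraction of each internode segment,
interpolated from the signed distance field — this sub-grid smoothing is
what makes the Born-ion error decrease monotonically under refinement
(4.7% → 1.1% → 0.3% at 0.1/0.05/0.025 nm). κ̄² = 8πf·c/kT applies in the
solvent region only (c from the ionic strength, 0.154 mol·dm⁻³ for saline
runs); Dirichlet boundaries use the single-center Debye–Hückel monopole.
G_pol = ½Σqᵢ(φ_solv − φ_ref)(rᵢ) with φ_ref from a uniform-ε_in solve on
the same grid and charge spread (trilinear), so the grid self-energy
cancels exactly.

**Nonpolar term.** γ·SASA with γ = 0.0227 kJ·mol⁻¹·Å⁻² and zero offset
(common MM-PBSA practice; the source publication states neither γ nor the
PB parameters, which is why absolute published ΔG values are not
reproducible even in principle). SASA is Shrake–Rupley with a deterministic
Fibonacci sphere lattice (960 points/atom, probe 0.14 nm); the single-
sphere quadrature error is below 1%.

## Numerical/degenerate-input policy

Empty selections, empty trajectories, zero-mass selections, coincident
atoms in pair sums, sub-3-atom or collinear superpositions, peptides under
5 residues (secondary structure), and r_max beyond the minimum-image range
all raise typed errors rather than returning silent zeros. All stochastic
steps take explicit integer seeds, default 0; identical (spec, seed) inputs
give bit-identical structures, ensembles, and output files.

## Known limitations

* Initial geometries (helical PEO, uniform-φ/ψ peptides, tetrahedral side
  chains) are idealized starting structures, not energy-minimized ones.
* The secondary-structure assigner is purely pattern-based; it agrees with
  propensity-based assigners on ideal helices and extended chains but can
  differ on distorted intermediates.
* The PB solver assumes a cubic grid and a two-dielectric map; no ion
  exclusion (Stern) layer is modelled.
* Ensembles have no time correlation; estimator variances, not
  autocorrelation times, are the only uncertainty model.
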