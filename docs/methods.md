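# Methods

This note records the models behind `fibnp`, the parameters that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Twist-angle statistic

Each peptide's orientation is reduced to the displacement vector between the
Cα atoms of two marker residues, pointing from residue 32 toward residue 18.
For consecutive peptides j, j+1 of one protofilament the local twist is the
unsigned angle φ between their vectors, computed as
`atan2(|v₁×v₂|, v₁·v₂)` — identical to the arccos of the normalized dot
product but exact for near-parallel vectors, which matters when recovering
small twists to 10⁻⁶ degree. The summary statistic is the grand mean over
the inner peptide pairs (ordinals 4–25 inclusive by default, dropping the
terminal peptides to avoid boundary effects; 29 peptides therefore give 22
peptides and m = 21 pairs) and over the final frames of the trajectory
(500 by default; at the 10 ps frame spacing that is 5 ns). Distributions
pool all frame × pair angles; bin percentages use the half-open partition
[0,10), [10,20), [20,180] with boundary ties going upward, and the
histogram bin width defaults to 1°.

Two deliberate conventions: angles are **unsigned** (no handedness — the
statistic cannot distinguish left- from right-handed twist) and the raw 3-D
angle is used without projecting onto the plane perpendicular to the fibril
axis. Consequences: the estimator is exactly invariant under rigid motion
of each frame, and under isotropic coordinate noise it is biased upward
(an angle near 0 can only fluctuate up); the bias grows with the noise
amplitude, which the test suite asserts as a monotone ordering over
σ ∈ {0, 0.1, 0.3} Å.

## Stochastic SASA and contact areas

SASA uses the Monte-Carlo variant of the Shrake–Rupley construction. Each
target atom i is surrounded by a sphere of radius r_i + r_probe
(probe 1.4 Å); n points (default 500) are drawn uniformly on that sphere by
Marsaglia sampling from a seeded generator; a point is accessible iff it
lies outside the probe-expanded sphere of every other target atom and of
every occluder atom, and the accessible fraction multiplies the exact area
4π(r_i + r_probe)². Points are generated in each atom's local frame and
depend only on (n_atoms, n_points, seed) — never on geometry — so an
evaluation with occluders reuses exactly the point set of the evaluation
without, and the SASA *difference* (the contact area) carries no extra
per-point noise. The binomial standard error
√(p(1−p)/n)·4πR² is propagated per atom and reported, so every downstream
comparison can use explicit Monte-Carlo tolerance bands; the test suite
checks the error model itself with a χ² test of 50 replicates against a
10⁶-point reference. Neighbour pruning uses a k-d tree and is exact with
respect to the brute-force definition. Whether occluder surfaces are
probe-expanded (standard, the default) or bare vdW is a config flag kept
for sensitivity checks. vdW radii default to the Bondi element set and can
be overridden per atom via the PQR radius column.

Contact areas are frame-averaged over the trajectory tail; an optional
frame stride evenly subsamples those frames so that frame-averaged SASA on
systems of a few thousand atoms stays at desk scale (the default pipeline
uses every 20th of the last 500 frames for surface and energy stages; the
stride is a sampling choice reported in the output, and stride 1 reproduces
full averaging).

Heavy-atom contacts use an inclusive, center-to-center 5 Å cutoff; only the
counted group is filtered to heavy atoms.

## Nonbonded energies

Interaction energies sum inter-group pairs only (no intra-group terms, no
bonded exclusions — this is an interaction-energy contract for post-hoc
analysis, not a force field). The Coulomb term divides by a uniform
dielectric ε = 78.5 to mimic water and, by default, has **no** distance
cutoff; the 10 Å truncation applies to the Lennard-Jones (12,6) term only,
with Lorentz–Berthelot-style combining (ε_ij geometric, r_min additive from
stored half-values) and plain truncation (no switching function). The
Coulomb constant is fixed at 332.0636 kcal·Å/(mol·e²), the potential
constant at 14.3996 V·Å/e (CODATA-derived MD conventions).

A uniform dielectric cannot reproduce ionic screening: a net-charged
structure dominates the far field at any pose. `NonbondedParams.coulomb_cutoff`
therefore enables a short-range electrostatics variant that serves as the
package's proxy for the salt-screened local field; qualitative
sign-structure analyses (is a charged NP locally attracted to the acidic
β-sheet face and repelled at the Lys-bearing tip?) use that variant, and
the synthetic fibril (net −3 e per peptide, −174 e total) makes the
unscreened form negative for a positive NP at every pose — both behaviors
are implemented and both are asserted in the tests. Per-residue
decomposition attributes each pair's energy to the residue of the
second-group atom; the shares sum to the totals by construction.

LJ parameters come from a user-supplied TSV keyed by (residue, atom name)
with an element-level fallback; the synthetic builders assign a schematic
element-level set (e.g. C: 0.07 kcal/mol, r_min/2 2.0 Å; S: 0.45, 2.0;
Au: 0.2, 1.66). These are plausible magnitudes for validation geometry, not
a curated force field; absolute LJ energies on synthetic structures are
meaningful only relative to each other.

## Synthetic fibril

The fibril is a deliberately idealized cross-β lattice: each peptide is a
U-shaped 40-residue Cα trace (Aβ40 sequence; strands along x with 3.47 Å
Cα spacing, 9.6 Å between the two strands, one pseudo-sidechain bead per
residue at 1.5 Å) lying in a plane perpendicular to the +z fibril axis, so
the residue-18→32 marker vector is exactly axis-perpendicular in the
untwisted template. Peptide j+1 is peptide j translated by the 4.8 Å
canonical cross-β rise and rotated by the imposed twist about the axis;
29 peptides span 28 × 4.8 = 134.4 Å = 13.44 nm. The second protofilament
is the first rotated 180° about the axis, offset 7.5 Å laterally so the
two columns do not overlap. Sidechain beads carry integer residue charges
(Asp/Glu −1, Lys/Arg +1, His and termini neutral), giving −3 e per peptide.
Residues 1–8 can optionally be replaced by a seeded random-walk coil to
mimic the disordered N-terminus; the default keeps the ordered geometry,
which is the validation baseline (the marker residues 18/32 are unaffected
either way).

What this emulates: the counting structure (29 peptides/protofilament, two
protofilaments, 13–14 nm span), a controllable ground-truth twist, the
charge topology of the β-sheet surface (exposed Glu22/Asp23, Lys16/Lys28)
and the net-negative fibril. What it does not: real backbone geometry,
sidechain packing, the 2LMO fold, hydrogen atoms, solvent. Passing tests
therefore demonstrate correctness of the estimators on known-truth
geometry, not fidelity of any absolute area/energy to the experimental
fibril.

## Synthetic nanoparticles

The gold core is an icosahedron surface uniformly tiled with equilateral
triangles of side exactly b₀ = 2.74 Å (rigid-bond convention), so every
bonded Au–Au distance equals b₀ to machine precision — a sphere projection
cannot do this, and the "icosahedral shell" is taken literally. The
subdivision frequency is the integer bringing the circumscribed diameter
closest to the requested 2.2 nm (frequency 4: 162 atoms, 20.85 Å). Gold
atoms carry exactly zero charge. 90 thiol anchor sites sit on a
deterministic spherical Fibonacci lattice 2.4 Å above the shell
("homogeneously distributed" is realized deterministically for
reproducibility); mixed compositions interleave types evenly along the
lattice ordering (largest-deficit round robin), while Janus placement
sorts sites by z so each of the two types occupies one hemisphere exactly.
Ligands are schematic collinear bead chains with correct net charges:
PEG-ammonium (+1), PEG-sulfonate (−1), PEG-NQTrp (neutral, rigid planar
six-bead ring), and the peptide ligand Cys-Glu-Leu-Val-Phe-Phe-Ala-Lys-Lys
— the charge inversion (Lys/Arg→Glu, Glu/Asp→Lys) of the fibril's exposed
Lys-Leu-Val-Phe-Phe-Ala-Glu-Asp motif, net +1. Recipe net charges: Pos and
Pep +90 e, PosNQ +80 e, NegNQ −80 e, Janus (45/45, config-exposed) 0 e.
Torsional realism and ligand flexibility are out of scope.

## Trajectories and posing

Synthetic trajectories add i.i.d. Gaussian noise per coordinate around the
reference structure, frame spacing 10 ps (500 frames = 5 ns), optionally
with cumulative rigid drift of a tagged sub-structure; identical seeds give
bit-identical frames. `place_near` poses an NP along the outward direction
through a target selection (the Glu22/Asp23 beads of the mid peptides for
the "acidic face", the terminal peptide's Lys28 bead for the "tip" — Lys28
rather than Lys16 because Lys16 sits within ~10 Å of Glu22/Asp23 in the
template, which would mix the local field) and backs off along that
direction until the closest center-to-center distance is at least the
requested gap, so poses are clash-free and deterministic.

## Pipeline, determinism, degenerate inputs

`run_pipeline` wires generate → analyze → report; every stochastic stage
takes an explicit seed, reports carry a config hash and stage log instead
of timestamps, and identical configs produce byte-identical JSON. Analyses
error loudly rather than degrade: trajectories shorter than the requested
tail, inner ranges outside the peptide count, missing charges/radii/LJ
parameters, overlapping selections, zero pair distances and zero-length
marker vectors all raise with the offending atoms or stage named. Grid
points within 0.5 Å of an atom center are masked NaN in potential grids.
PDB writing enforces strict serials (≤ 99,999 atoms), 3-decimal
coordinates and a TER record after each chain; residue numbering is 1-based
and file-verbatim throughout.

## Known limitations

* Unsigned angles cannot detect twist handedness or distinguish a +θ from
  a −θ deformation.
* The uniform-dielectric Coulomb model has no ionic screening; absolute
  electrostatic magnitudes on net-charged systems are pose- and
  size-dependent and only sign/ordering statements are meaningful.
* Synthetic geometry is schematic; absolute SASA/contact-area/energy values
  on synthetic structures validate the estimators, not the real system.
* The peptide-per-chain convention caps a single PDB file at 62 chains
  (single-character chain ids).
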