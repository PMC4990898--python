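# Methods

## The coarse-grained lattice model

Each tubulin monomer is a point mass; an αβ-heterodimer is two beads, the
β bead one monomer rise (41 Å) above the α bead. The canonical N-S
lattice (N = 13 protofilaments, S = 3-start) places strand *s* at azimuth
2πs/N with axial offset s·S·h/N (h = 41 Å monomer rise), dimers stacked
at the 82 Å repeat, on a 250 Å cylinder. These lattice constants are
textbook tubulin values and are configuration defaults; with them the
195-dimer model measures 134.4 nm end to end. Dimer *d* lives on strand
*d* mod N at level *d* div N, so consecutive dimer indices trace the
lateral winding — the same order the filament's single dimer strand
follows after the seam is rewired.

**End-to-end length** is the bead z-extent plus one full monomer rise
(half a monomer at each end), accounting for the axial size the point
masses do not carry. The half-per-end split is this package's choice of
the end adjustment; it reproduces the ~135 nm length of the 195-dimer
model.

**Registry** (dimers per helical turn) is round(πD/s) for diameter D and
lateral spacing s, ties rounded away from zero; measured on a bead model
it is round(2π/⟨Δφ⟩) over laterally adjacent dimer pairs. The analytic
filament height at coil separation p is H = (n−1)·p/m + 82 Å with
m = registry — linear in p at fixed D, so height extremes sit at the
corners of any (D, p) range.

## Restraints and the optimization engine

Harmonic restraints use **E = k·Δ²** (no ½), matching how restraint
force constants are conventionally printed; every equilibrium-variance
formula in the tests therefore uses the effective spring 2k. Five kinds:
distance, angle, torsion (minimum-image angular deviation in
(−180°, 180°]), cylindrical (distance from the z axis), positional.
Gradients are analytic and finite-difference-verified for all kinds.

The maintenance set for an N-S lattice is measured off the ideal
lattice: intra-dimer distances, inter-dimer longitudinal distances
(β_n : α_{n+N}), lateral α–α/β–β distances, the seam's α–β contacts, and
three families of stiffeners that make the shell rigid up to rigid-body
motion:

- *chain angles and torsions* along the lateral α- and β-bead chains —
  distance restraints alone let the shell shear (every pair distance can
  be satisfied while levels twist against each other);
- *dimer-axis angles* between the intra-dimer axis and the lateral link —
  without them the β chain can slide tangentially relative to the α
  chain once longitudinal contacts are gone (the heterodimer axis is
  assumed to stay parallel to the cylinder axis);
- *cross-level twist torsions* spanning each longitudinal link — the
  vertical distance links resist level-against-level rotation only at
  fourth order, so a plain distance network lets levels rotate at
  near-zero cost.

Distance force constants default to 10 kcal/mol/Å² and the
angle/torsion constants to 100 kcal/mol/rad². These are model-building
stiffnesses, not physical couplings: they only need to hold the target
geometry, and the angular constants must be stiff enough that the
pitch-setting modes (which map small angular strains into large axial
motions) are well conditioned.

**Minimization** is adaptive-step steepest descent (trust radius from
0.1 Å, halved on uphill trials, grown 20% on acceptance, capped at 1 Å;
termination on |ΔE| below tolerance, default 0.001 kcal/mol). The
filament transition's collective modes — a 195-dimer strand re-winding
around the cylinder — are far too ill-conditioned for steepest descent
alone, so protocol stages may instead use an L-BFGS quasi-Newton polish;
the model-building protocol is SD → NVT → quasi-Newton.

**Dynamics** is BAOAB-split Langevin leapfrog (friction 1/ps by
default, dt = 0.002 ps, masses in amu, kB = 0.0019872 kcal/mol/K,
1 kcal/mol = 418.4 amu Å²/ps²); trajectories are bit-identical for a
given seed. The thermostat satisfies equipartition: mean kinetic energy
per degree of freedom → kB·T/2 and the positional variance of a
k-restrained coordinate → kB·T/(2k). At friction 1/ps the position
autocorrelation time of a unit-mass, k = 1 oscillator is ~2 ps, so
tests that check these averages at 10⁵ steps use friction 20/ps to
decorrelate samples; this changes sampling efficiency, not the
stationary distribution.

## The 13-3 → helical filament transition

1. **Seam rewiring.** The seam's α–β contacts (α_n : β_{n+1},
   β_n : α_{n+1+N}) are dropped; α–α and β–β contacts between the last
   and first strands are added with *interior* lateral-chain geometry as
   targets (distance, chain angle/torsion, dimer axis). Seam-spanning
   stiffeners that carried 13-3 targets are retargeted. Relaxing the
   rewired, longitudinally-unbonded lattice yields the
   lateral-contact-preserving filament: an unchanged 250 Å diameter,
   coil separation S·h = 123 Å, and a 41 Å (one monomer) axial gap
   between vertically adjacent dimers.
2. **Longitudinal removal** deletes all inter-dimer longitudinal
   restraints (distance links and twist torsions); intra-dimer links
   remain.
3. **Cylindrical expansion** adds per-bead cylindrical restraints at the
   target radius (k = 10 kcal/mol/Å², kept through the later stages —
   the filament is assumed to keep a uniform diameter). Lateral contact
   spacing is held by the lateral restraints, so the strand re-winds and
   the registry grows — 13 → 21 at the 40.4 nm mean filament diameter.
4. **Graded stretch.** First-order distance restraints between dimers
   one turn apart (α_n:α_{n+m}, β_n:β_{n+m}) ramp linearly from 107 Å to
   the target coil separation over 10 increments (the count is this
   package's choice; the ramp endpoints are the model's), with
   second-order restraints between dimers two turns apart pinned at
   exactly twice the first-order target, which keeps the lengthening
   uniform along the filament (relative SD of the per-pair separations
   ≲ 1%).

Every stage runs the SD/NVT(100 K)/quasi-Newton protocol; all stage
seeds derive from the single pipeline seed.

## EM parameter ranges

The negative-stain EM measurements behind the filament geometry are not
redistributable here, so the configuration ships a calibrated stand-in:
diameter 39.0–41.2 nm (mean 40.4 nm) and coil separation 18.6–23.9 nm
(mean 19.3 nm). The calibration is pinned by the model's own anchors —
the mean diameter gives registry 21, the mean coil separation is the
193 Å stretch target, and the corners of the range give analytic
filament heights of exactly 180 and 240 nm for the 195-dimer model
(min = 194·(186/21) + 8.2 nm, max = 194·(239/20) + 8.2 nm). Measured
ranges can be substituted through the YAML config without touching code.

## Atomic reconstruction

Templates (real monomer structures, or the deterministic toys bundled
for testing) are translated monomer-by-monomer onto bead centres of
mass, axes parallel to z. Ten conserved reference C-α atoms per dimer
(α: R121, K304, V324, P364, D424; β: P86, V126, G146, P311, F415) are
extracted in fixed residue order. Each dimer is then rotated rigidly
about its own vertical axis to minimize Σᵢ(ρᵢ(θ) − (Rᵢ + R_cyldiff))²,
where ρᵢ is the reference atom's distance from the global cylinder axis,
Rᵢ its radius in the azimuthally oriented 13-3 placement, and R_cyldiff
the uniform radial increase (77 Å from 13-3 to the mean filament). The
solution is found on a coarse angular grid and refined by bounded scalar
minimization — a 1-D problem because the dimer axis is assumed to stay
vertical and on-cylinder; the soft-then-stiff (1 then 900 kcal/mol/Å²)
two-stage schedule of restrained optimizers maps onto coarse-grid then
tight refinement of the same objective, whose optimum is
k-independent. The full dimer follows by Kabsch least-squares
superposition onto the reoriented reference points; every per-dimer
operation is a proper rigid transform, so internal geometry is exact,
mirror solutions are excluded by construction, and the radial
(luminal-vs-outer) ordering of the reference residues is preserved.
Reconstructing the 13-3 model itself with R_cyldiff = 0 reproduces the
oriented placement to numerical precision.

## Electrostatic interaction energies

For a tetramer (two dimers at a named interface) the per-snapshot
interaction energy is E(tetramer) − E(dimer1) − E(dimer2), evaluated
for:

- **Coulomb**: Σ k·qᵢqⱼ/(ε_in·rᵢⱼ), k = 332.0636 kcal·Å/(mol·e²),
  ε_in = 1, infinite cutoff;
- **GB solvation**: Still's interpolation
  ΔG = −½(1/ε_in − 1/ε_out)·k·Σᵢⱼ qᵢqⱼ/f_GB,
  f_GB = √(r² + BᵢBⱼ·exp(−r²/4BᵢBⱼ)), ε_out = 80, with effective Born
  radii from Hawkins–Cramer–Truhlar pairwise descreening (neighbor radii
  scaled 0.8; an isolated atom's Born radius is exactly its intrinsic
  radius, so the single-ion energy matches the Born equation). This is
  an analytic pairwise stand-in chosen for its transparent
  decomposition; it is not a grid-based GB implementation, and no
  absolute energies from such calculations are reproduced here — the
  model's value is the Coulomb/solvation split and its sign structure
  (like-charged dimers: repulsive Coulomb term, opposing negative
  solvation term, near-zero total at large separation).
- **Nonpolar**: γ·SASA with γ = 0.03 kcal/mol/Å², probe 1.4 Å, SASA by
  deterministic Shrake–Rupley with a fixed 960-point golden-spiral set
  per atom. The headline "electrostatic interaction" is defined as
  Coulomb + solvation only; the nonpolar subtraction is computed and
  reported separately.

The identity E_total = E_Coul + E_solv holds exactly per snapshot by
construction. Atoms engulfed entirely inside a neighbor sphere are not
specially cased in the descreening integral (irrelevant at the
separations of these fixtures) — a known limitation.

**Sampling.** Snapshot ensembles come from Langevin dynamics at 300 K
under positional tethers (1 kcal/mol/Å²) on the selected backbone atoms
plus a soft-sphere overlap repulsion; counts follow the ensemble plan
(per replica: (run length − equilibration)/save interval; 1 ns runs with
1 ps saves and 10 ps discard give 990 snapshots per replica, 4950 per
tetramer system over 5 replicas). Replica and pooled statistics use the
sample (n−1) standard deviation; with equal replica sizes the pooled
mean equals the mean of replica means.

## Synthetic data

Toy monomers are ~50 pseudo-atoms placed by seeded rejection sampling
(minimum separation 5 Å) in a cylinder of the monomer's real dimensions
(41 Å tall, 50 Å wide), labelled so the five reference residues of each
kind are present, with partial charges summing to −10 e (tubulin
monomers are strongly acidic; a zero-sum scheme exists for separability
tests) and intrinsic radii of 1.5–2.0 Å. Toy tetramers place two such
dimers in the exact relative geometry of the four nearest-neighbor
interfaces (13-3 lateral, 13-3 seam, longitudinal, filament lateral)
derived from the lattice constants. The toys reproduce sizes, labels,
charge bookkeeping and interface geometry — not protein shape, packing,
sequence, or real charge distributions — so passing energy tests
demonstrates correct decomposition mechanics, limits and sign structure,
not biological energy values.

## Problem sizes and determinism

The full transition runs 195 dimers (390 beads, ~2500 restraints) in a
few minutes; test-suite variants use 26–105 dimers, which preserve every
qualitative observable (registry, coil targets, uniformity) at a
fraction of the cost. The analytic grid covers the EM ranges at 0.1 nm
increments (~1200 points, instantaneous). All stochastic paths flow
from one user seed through derived stage seeds; identical seeds give
byte-identical outputs.

## Known limitations

- The coarse model is restraints-only: no excluded volume between beads
  and no force field, as befits geometric model building.
- The GB stand-in shares the decomposition structure, dielectrics and
  surface-tension settings of grid-based GB models but not their
  absolute energies; comparisons should stay within this package.
- The stretch schedule's 107 Å starting target is the mean-geometry
  value; for filaments whose target coil separation is below it the
  ramp starts at the target itself.
- Sequence identity depends on the stated convention (BLOSUM62, affine
  10/0.5 gaps, denominator excluding terminal gap columns); other
  conventions shift identities by a point or two.
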