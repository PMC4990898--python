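# helifil

Modelling the transition of tubulin **13-3 microtubules** into **helical
filaments** — the storage/transport form of tubulin observed in
foraminiferan protists — and estimating the electrostatics of the
inter-dimer contacts that make the transition plausible.

Microtubules are cylinders of 13 protofilaments (longitudinal chains of
αβ-tubulin heterodimers) joined by lateral α–α/β–β contacts, with one
"seam" where α meets β because the lattice winds up three monomers per
turn. In foram helical filaments the longitudinal contacts are lost while
the lateral contacts persist, leaving a single laterally-bonded dimer
strand wound as a helix whose coarse geometry (cylinder diameter,
distance between coils) is known only from low-resolution negative-stain
EM. `helifil` provides the full modelling chain:

- **`helifil.lattice`** — parametric N-S point-mass lattices (one bead
  per tubulin monomer), closed-form helix geometry: registry
  m = round(πD/s) (dimers per turn at diameter D and lateral spacing s),
  rise per step p/m, overall height H = (n−1)·p/m + 82 Å, and grid scans
  over EM parameter ranges.
- **`helifil.restraints`** — typed harmonic restraints (distance, angle,
  torsion, cylindrical, positional) with the convention **E = k·Δ²**,
  analytic gradients, adaptive steepest-descent and quasi-Newton
  minimization, and seeded Langevin (BAOAB) NVT dynamics.
- **`helifil.transition`** — the 13-3 → helical-filament protocol: seam
  rewiring (α–β → α–α/β–β), longitudinal-restraint removal, cylindrical
  expansion (registry 13 → 21 at the mean EM diameter), and graded helix
  stretching (one-turn dimer separation 107 → 193 Å, with two-turn
  restraints at exactly twice that to keep the lengthening uniform).
- **`helifil.reconstruct`** — atomic-detail reconstruction: monomer
  templates placed on bead centres of mass, 10 conserved reference C-α
  atoms per dimer (α: R121, K304, V324, P364, D424; β: P86, V126, G146,
  P311, F415) rotated about the dimer axis to cylindrical targets
  R_i + R_cyldiff, full dimers rebuilt by Kabsch least-squares
  superposition.
- **`helifil.energy`** — per-snapshot inter-dimer electrostatics
  E_int = E(tetramer) − E(dimer1) − E(dimer2), split into a Coulomb term
  (infinite cutoff, ε_in = 1) and a Still-type pairwise generalized-Born
  solvation term (ε_out = 80), with a γ·SASA nonpolar term (γ = 0.03
  kcal/mol/Å², reported separately), restrained-ensemble sampling
  (1 kcal/mol/Å² backbone tethers) and per-replica + pooled statistics.
- **`helifil.synth`** — deterministic toy monomers/dimers/tetramers for
  the four nearest-neighbor interfaces (13-3 lateral, 13-3 seam,
  longitudinal, filament lateral).

Everything is seed-deterministic; internal units are Å and kcal/mol
(CLI geometry options in nm).

## Worked example

```python
from helifil import LatticeSpec, build_mt_lattice, end_to_end_length
from helifil.transition import mt_to_hf_pipeline

spec = LatticeSpec()          # 13 protofilaments, 3-start, 195 dimers
mt = build_mt_lattice(spec)
print(len(mt), end_to_end_length(mt, spec.monomer_rise) / 10)

hf, geo = mt_to_hf_pipeline(
    spec, {"diameter": 404.0, "coil_separation": 193.0}, seed=1
)
print(geo.registry, round(geo.coil_separation, 1),
      round(geo.height / 10, 1))
```

prints

```
390 134.35384615384615
21 192.9 186.3
```

— the 195-dimer microtubule is 390 beads and ~134 nm long; after the
transition to the mean EM filament geometry the registry has risen from
13 to 21 dimers per turn, the coil separation sits on its 19.3 nm target
and the filament is ~186 nm tall (inside the 180–240 nm span the EM
parameter ranges allow, i.e. filaments are never shorter than the
microtubules they come from).

The same from the shell:

```
helifil build-mt
helifil to-hf --seed 1
helifil grid-scan --step 0.1
helifil energy --interface lateralHF --replicas 5 --seed 1
```

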