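"""Synthetic toy structures emulating tubulin monomers, dimers and the
four nearest-neighbor tetramer interfaces.

The toy monomer is a pseudo-atomic stand-in for a tubulin monomer: ~50
C-alpha pseudo-atoms placed deterministically inside a cylinder of the
monomer's real dimensions (41 A tall, ~50 A wide), labelled with residue
numbers that include the conserved reference residues used by the
filament reconstruction, and carrying partial charges and intrinsic
radii.  It reproduces the sizes, labels and charge bookkeeping real
structures provide — not protein shape, packing or sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import ALPHA, BETA, LatticeSpec, build_mt_lattice
from .reconstruct import (
    ALPHA_REFERENCE_RESIDUES,
    BETA_REFERENCE_RESIDUES,
    place_on_beads,
)
from .structure import AtomicStructure

__all__ = [
    "ToyTemplateSpec",
    "make_toy_monomer",
    "make_toy_dimer",
    "make_toy_tetramer",
    "TETRAMER_INTERFACES",
]

TETRAMER_INTERFACES = ("lateral13", "lateralHF", "longitudinal", "seam")


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class ToyTemplateSpec:
    """Toy monomer parameters.

    ``charge_scheme``: ``net_negative`` (total charge ``net_charge``,
    tubulin monomers are strongly acidic) or ``zero_sum`` (neutral).
    ``min_separation`` keeps pseudo-atoms from overlapping.
    """

    n_atoms: int = 50
    height: float = 41.0
    width: float = 50.0
    charge_scheme: str = "net_negative"
    net_charge: float = -10.0
    radius_range: tuple = (1.5, 2.0)
    min_separation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 12:
            raise SynthError("toy monomer needs at least 12 atoms")
        if self.charge_scheme not in ("net_negative", "zero_sum"):
            raise SynthError(f"unknown charge scheme {self.charge_scheme!r}")


def _reference_set(kind: int):
    return ALPHA_REFERENCE_RESIDUES if kind == ALPHA else (
        BETA_REFERENCE_RESIDUES
    )


def make_toy_monomer(spec: ToyTemplateSpec, kind: int) -> AtomicStructure:
    """Deterministic pseudo-atomic monomer, centre of mass at the origin,
    axis along z, carrying the five reference residues of its kind."""
    if kind not in (ALPHA, BETA):
        raise SynthError(f"unknown monomer kind {kind!r}")
    rng = np.random.default_rng((int(spec.seed), int(kind)))
    n = spec.n_atoms
    half_h = spec.height / 2.0
    rad = spec.width / 2.0

    coords = np.zeros((n, 3))
    placed = 0
    while placed < n:
        cand = rng.uniform(-1, 1, size=3)
        xyz = np.array(
            [cand[0] * rad, cand[1] * rad, cand[2] * half_h]
        )
        if math.hypot(xyz[0], xyz[1]) > rad:
            continue
        if placed and np.min(
            np.linalg.norm(coords[:placed] - xyz, axis=1)
        ) < spec.min_separation:
            continue
        coords[placed] = xyz
        placed += 1
    coords -= coords.mean(axis=0)

    refs = _reference_set(kind)
    other = {rid for _, rid in _reference_set(1 - kind)}
    taken = {rid for _, rid in refs}
    res_ids = np.zeros(n, dtype=int)
    res_names = np.empty(n, dtype="U3")
    for i, (rname, rid) in enumerate(refs):
        res_ids[i] = rid
        res_names[i] = rname
    next_id = 1
    generic = ("GLY", "ALA", "SER", "LEU", "GLU")
    for i in range(len(refs), n):
        while next_id in taken or next_id in other:
            next_id += 1
        res_ids[i] = next_id
        res_names[i] = generic[i % len(generic)]
        taken.add(next_id)

    charges = rng.uniform(-0.6, 0.4, size=n)
    target = spec.net_charge if spec.charge_scheme == "net_negative" else 0.0
    charges += (target - charges.sum()) / n
    radii = rng.uniform(*spec.radius_range, size=n)

    return AtomicStructure(
        names=np.full(n, "CA"),
        res_names=res_names,
        res_ids=res_ids,
        chains=np.full(n, "A"),
        elements=np.full(n, "C"),
        coords=coords,
        charges=charges,
        radii=radii,
        backbone=np.ones(n, dtype=bool),
    )


def toy_templates(spec: ToyTemplateSpec) -> dict:
    """Template dictionary keyed by bead kind, as the reconstruction
    operations expect."""
    return {
        ALPHA: make_toy_monomer(spec, ALPHA),
        BETA: make_toy_monomer(spec, BETA),
    }


def make_toy_dimer(
    spec: ToyTemplateSpec,
    lattice: LatticeSpec | None = None,
    chains: tuple = ("A", "B"),
    segment: int = 0,
) -> AtomicStructure:
    """An alpha-beta heterodimer: beta monomer one monomer rise above the
    alpha monomer, dimer centre of mass at the origin."""
    if lattice is None:
        lattice = LatticeSpec(n_dimers=1)
    h = lattice.monomer_rise
    alpha = make_toy_monomer(spec, ALPHA).translated((0, 0, -h / 2.0))
    beta = make_toy_monomer(spec, BETA).translated((0, 0, +h / 2.0))
    alpha = alpha.relabeled(chain=chains[0], segment=segment)
    beta = beta.relabeled(chain=chains[1], segment=segment)
    return AtomicStructure.concat([alpha, beta])


def _hf_geometry_defaults():
    # mean filament: diameter 404 A, coil separation 193 A over 21 dimers
    return {"diameter": 404.0, "coil_separation": 193.0, "registry": 21}


def make_toy_tetramer(
    interface: str,
    spec: ToyTemplateSpec | None = None,
    lattice: LatticeSpec | None = None,
    hf_params: dict | None = None,
) -> AtomicStructure:
    """Two toy dimers in the relative geometry of a named interface.

    ``lateral13``  adjacent strands of the 13-3 lattice (same level);
    ``seam``       the 13-3 seam contact (last to first strand, one level
                   up: an axial offset of minus half a dimer repeat plus
                   the per-turn rise);
    ``longitudinal`` same strand, adjacent levels (purely axial, one
                   dimer repeat);
    ``lateralHF``  adjacent positions on the helical filament (filament
                   diameter, one of ``registry`` steps per turn).

    Dimer 1 has chains A (alpha) and B (beta); dimer 2 chains C and D, so
    the result feeds the interaction-energy selections directly.
    """
    if spec is None:
        spec = ToyTemplateSpec()
    if lattice is None:
        lattice = LatticeSpec(n_dimers=1)
    if interface not in TETRAMER_INTERFACES:
        raise SynthError(f"unknown interface kind {interface!r}")

    r = lattice.radius
    n = lattice.n_protofilaments
    rise_step = lattice.rise_per_step

    if interface == "lateralHF":
        hf = dict(_hf_geometry_defaults())
        if hf_params:
            hf.update(hf_params)
        r = hf["diameter"] / 2.0
        dphi = 2.0 * math.pi / hf["registry"]
        dz = hf["coil_separation"] / hf["registry"]
    elif interface == "lateral13":
        dphi = 2.0 * math.pi / n
        dz = rise_step
    elif interface == "seam":
        dphi = 2.0 * math.pi / n
        # last strand to first strand one level up
        dz = lattice.dimer_repeat - (n - 1) * rise_step
    else:  # longitudinal
        dphi = 0.0
        dz = lattice.dimer_repeat

    def place(dphi_i, z, chains, segment):
        d = make_toy_dimer(spec, lattice, chains=chains, segment=segment)
        c, s = math.cos(dphi_i), math.sin(dphi_i)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pos = np.array([r * math.cos(dphi_i), r * math.sin(dphi_i), z])
        return d.transformed(rot, pos)

    dimer1 = place(0.0, 0.0, ("A", "B"), 0)
    dimer2 = place(dphi, dz, ("C", "D"), 1)
    return AtomicStructure.concat([dimer1, dimer2])
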