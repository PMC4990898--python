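"""Parametric tubulin lattice construction and closed-form helix geometry.

A microtubule is modelled as an N-start cylindrical lattice of point-mass
beads, one bead per tubulin monomer (two beads per alpha-beta heterodimer).
The canonical architecture is "13-3": 13 protofilaments with a longitudinal
offset of 3 monomers per turn, which places a seam between the last and the
first protofilament where alpha contacts beta laterally.

All lengths are in Angstrom internally; reporting helpers convert to nm.
The cylinder axis is +z, and within a dimer the beta bead sits above the
alpha bead (plus-end-up convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSpec",
    "BeadModel",
    "HelixGeometry",
    "build_mt_lattice",
    "end_to_end_length",
    "registry_of",
    "model_registry",
    "lateral_arc_spacing",
    "analytic_hf_height",
    "grid_scan",
]


class LatticeError(ValueError):
    """Raised when a lattice specification violates an invariant."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (documented tie-break)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class LatticeSpec:
    """Geometric parameters of an N-start tubulin lattice.

    Parameters
    ----------
    n_protofilaments : int
        Number of protofilaments N (13 for the canonical microtubule).
    start_number : int
        Monomer offset S accumulated over one full turn (3 for "13-3").
    monomer_rise : float
        Axial height of one tubulin monomer, Angstrom.
    dimer_repeat : float
        Axial repeat of the alpha-beta heterodimer along a protofilament,
        Angstrom; must equal twice the monomer rise.
    lattice_diameter : float
        Diameter of the bead cylinder, Angstrom.
    n_dimers : int
        Total number of heterodimers in the model.
    seam_present : bool
        Whether the lattice carries the alpha-beta seam (true for any
        N-S lattice with S not a multiple of 2N).
    """

    n_protofilaments: int = 13
    start_number: int = 3
    monomer_rise: float = 41.0
    dimer_repeat: float = 82.0
    lattice_diameter: float = 250.0
    n_dimers: int = 195
    seam_present: bool = True

    def __post_init__(self) -> None:
        if self.n_protofilaments < 2:
            raise LatticeError("n_protofilaments must be >= 2")
        if not (0 < self.start_number < 2 * self.n_protofilaments):
            raise LatticeError(
                "start_number must satisfy 0 < S < 2*n_protofilaments"
            )
        if abs(self.dimer_repeat - 2.0 * self.monomer_rise) > 1e-6:
            raise LatticeError("dimer_repeat must equal 2 * monomer_rise")
        if self.n_dimers < 1:
            raise LatticeError("n_dimers must be >= 1")
        if self.lattice_diameter <= 0:
            raise LatticeError("lattice_diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.lattice_diameter / 2.0

    @property
    def rise_per_step(self) -> float:
        """Axial rise per lateral (protofilament-to-protofilament) step."""
        return self.start_number * self.monomer_rise / self.n_protofilaments


#: bead kind codes
ALPHA, BETA = 0, 1


@dataclass
class BeadModel:
    """Point-mass model: one bead per tubulin monomer.

    ``positions`` is (n_beads, 3) in Angstrom with the cylinder axis along z.
    ``kinds`` holds ALPHA/BETA codes, ``dimer_index`` and ``strand_index``
    are 0-based; reports use 1-based numbering.
    """

    positions: np.ndarray
    kinds: np.ndarray
    dimer_index: np.ndarray
    strand_index: np.ndarray
    masses: np.ndarray
    spec: LatticeSpec | None = None
    seam_present: bool | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise LatticeError("positions must be (n, 3)")
        n = len(self.positions)
        for name in ("kinds", "dimer_index", "strand_index"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (n,):
                raise LatticeError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise LatticeError(f"masses must have length {n}")
        # exactly two beads (one alpha below one beta) per dimer
        for d in np.unique(self.dimer_index):
            sel = self.dimer_index == d
            if sel.sum() != 2:
                raise LatticeError(f"dimer {d} does not have exactly 2 beads")
            kinds = self.kinds[sel]
            if sorted(kinds.tolist()) != [ALPHA, BETA]:
                raise LatticeError(f"dimer {d} must have one alpha, one beta")
            za = self.positions[sel][kinds == ALPHA, 2][0]
            zb = self.positions[sel][kinds == BETA, 2][0]
            if zb <= za:
                raise LatticeError(
                    f"dimer {d}: beta bead must sit above alpha bead"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_dimers(self) -> int:
        return len(np.unique(self.dimer_index))

    @property
    def radii(self) -> np.ndarray:
        """Distance of every bead from the cylinder (z) axis."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    def dimer_com(self) -> np.ndarray:
        """(n_dimers, 3) centre of the two beads of each dimer, by index."""
        order = np.argsort(self.dimer_index, kind="stable")
        pos = self.positions[order]
        idx = self.dimer_index[order]
        out = np.zeros((self.n_dimers, 3))
        np.add.at(out, idx, pos)
        return out / 2.0

    def copy(self) -> "BeadModel":
        return replace(
            self,
            positions=self.positions.copy(),
            kinds=self.kinds.copy(),
            dimer_index=self.dimer_index.copy(),
            strand_index=self.strand_index.copy(),
            masses=self.masses.copy(),
        )


@dataclass(frozen=True)
class HelixGeometry:
    """Helical filament geometry.

    diameter and coil_separation in Angstrom; registry is the number of
    dimers per full turn; overall height in Angstrom.
    """

    diameter: float
    coil_separation: float
    registry: int
    rise_per_step: float
    height: float

    def __post_init__(self) -> None:
        if self.registry < 1:
            raise LatticeError("registry must be >= 1")
        if self.height <= 0:
            raise LatticeError("height must be > 0")
        if abs(self.coil_separation - self.registry * self.rise_per_step) > 1e-6:
            raise LatticeError(
                "coil_separation must equal registry * rise_per_step"
            )


def build_mt_lattice(spec: LatticeSpec, bead_mass: float = 100.0) -> BeadModel:
    """Construct the N-S point-mass lattice.

    Dimer d is placed on strand ``d % N`` at level ``d // N``; this winding
    order is also the lateral chain order used by the helical-filament
    transition.  Strand s is rotated by 2*pi*s/N about z and raised by
    s * S * monomer_rise / N, so the seam between strand N and strand 1
    carries the S-monomer offset.
    """
    n = spec.n_protofilaments
    d_idx = np.arange(spec.n_dimers)
    strand = d_idx % n
    level = d_idx // n

    phi = 2.0 * np.pi * strand / n
    z_alpha = strand * spec.rise_per_step + level * spec.dimer_repeat
    r = spec.radius

    pos = np.empty((2 * spec.n_dimers, 3))
    kinds = np.empty(2 * spec.n_dimers, dtype=int)
    # alpha bead first, beta bead monomer_rise above it
    pos[0::2, 0] = r * np.cos(phi)
    pos[0::2, 1] = r * np.sin(phi)
    pos[0::2, 2] = z_alpha
    pos[1::2, :2] = pos[0::2, :2]
    pos[1::2, 2] = z_alpha + spec.monomer_rise
    kinds[0::2] = ALPHA
    kinds[1::2] = BETA

    return BeadModel(
        positions=pos,
        kinds=kinds,
        dimer_index=np.repeat(d_idx, 2),
        strand_index=np.repeat(strand, 2),
        masses=np.full(2 * spec.n_dimers, float(bead_mass)),
        spec=spec,
        seam_present=spec.seam_present,
    )


def end_to_end_length(model: BeadModel, monomer_extent: float) -> float:
    """Axial end-to-end length of a bead model, Angstrom.

    The bead z-extent is augmented by one full ``monomer_extent`` (half a
    monomer at each end) to account for the internal longitudinal dimension
    of the end monomers, which point masses do not carry.
    """
    if len(model) == 0:
        raise LatticeError("model is empty")
    if monomer_extent < 0:
        raise LatticeError("monomer_extent must be >= 0")
    z = model.positions[:, 2]
    return float(z.max() - z.min()) + monomer_extent


def lateral_arc_spacing(spec: LatticeSpec) -> float:
    """Arc length between adjacent protofilaments on the lattice cylinder."""
    return math.pi * spec.lattice_diameter / spec.n_protofilaments


def registry_of(diameter: float, lateral_spacing: float) -> int:
    """Dimers per full helical turn at the given diameter and lateral spacing.

    round(pi * D / spacing), ties rounded away from zero.
    """
    if diameter <= 0 or lateral_spacing <= 0:
        raise LatticeError("diameter and lateral_spacing must be > 0")
    return _round_half_away(math.pi * diameter / lateral_spacing)


def model_registry(model: BeadModel) -> int:
    """Registry measured from a bead model.

    The mean angular step between laterally adjacent dimers (adjacent strand
    indices at the same level) gives the dimers per full turn as
    round(2*pi / mean_dphi).  Works on ideal lattices and on expanded or
    stretched filaments, whose beads retain their strand/level bookkeeping.
    """
    com = model.dimer_com()
    n = int(model.strand_index.max()) + 1
    d_idx = np.arange(model.n_dimers)
    strand = d_idx % n
    phi = np.unwrap(np.arctan2(com[:, 1], com[:, 0]))
    dphi = []
    for d in d_idx[:-1]:
        if strand[d] + 1 == strand[d + 1]:  # same level, adjacent strands
            dphi.append(abs(phi[d + 1] - phi[d]))
    if not dphi:
        raise LatticeError("model has no adjacent-strand dimer pairs")
    mean_dphi = float(np.mean(dphi))
    # fold into (0, 2*pi) in case of unwrap offsets
    mean_dphi = mean_dphi % (2.0 * np.pi)
    return _round_half_away(2.0 * np.pi / mean_dphi)


def analytic_hf_height(
    diameter: float,
    coil_separation: float,
    spec: LatticeSpec,
    lateral_spacing: float | None = None,
) -> HelixGeometry:
    """Closed-form helical filament geometry at (D, p).

    registry m = round(pi*D / lateral_spacing); rise per lateral step p/m;
    overall height H = (n_dimers - 1) * rise + dimer_repeat.  The lateral
    spacing defaults to the arc spacing of the source lattice, i.e. lateral
    contacts are preserved while the cylinder dilates.
    """
    if coil_separation <= 0:
        raise LatticeError("coil_separation must be > 0")
    if lateral_spacing is None:
        lateral_spacing = lateral_arc_spacing(spec)
    m = registry_of(diameter, lateral_spacing)
    rise = coil_separation / m
    height = (spec.n_dimers - 1) * rise + spec.dimer_repeat
    return HelixGeometry(
        diameter=diameter,
        coil_separation=coil_separation,
        registry=m,
        rise_per_step=rise,
        height=height,
    )


def grid_scan(
    d_range: tuple[float, float],
    p_range: tuple[float, float],
    increment: float = 1.0,
    spec: LatticeSpec | None = None,
    mode: str = "analytic",
    lateral_spacing: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan helical filament heights over a (diameter, coil separation) grid.

    Ranges and the increment are in Angstrom (1.0 A = 0.1 nm, the published
    scan granularity).  Returns one row per grid point with columns
    ``D_nm, p_nm, registry, rise_A, height_nm``; ``cg`` mode additionally
    runs the full coarse-grained transition at each grid point and records
    the optimized model height in ``cg_height_nm``.
    """
    if spec is None:
        spec = LatticeSpec()
    if mode not in ("analytic", "cg"):
        raise LatticeError(f"unknown grid mode {mode!r}")
    if increment <= 0:
        raise LatticeError("increment must be > 0")
    d_lo, d_hi = d_range
    p_lo, p_hi = p_range
    if d_lo > d_hi or p_lo > p_hi:
        raise LatticeError("ranges must be ordered (lo, hi)")
    ds = np.arange(d_lo, d_hi + increment / 2, increment)
    ps = np.arange(p_lo, p_hi + increment / 2, increment)
    if len(ds) == 0 or len(ps) == 0:
        raise LatticeError("empty grid")

    rows = []
    for d in ds:
        for p in ps:
            geo = analytic_hf_height(d, p, spec, lateral_spacing)
            row = {
                "D_nm": d / 10.0,
                "p_nm": p / 10.0,
                "registry": geo.registry,
                "rise_A": geo.rise_per_step,
                "height_nm": geo.height / 10.0,
            }
            if mode == "cg":
                from .transition import mt_to_hf_pipeline

                _, measured = mt_to_hf_pipeline(
                    spec, {"diameter": d, "coil_separation": p}, seed=seed
                )
                row["cg_height_nm"] = measured.height / 10.0
            rows.append(row)
    return pd.DataFrame(rows)


def grid_summary(table: pd.DataFrame) -> dict:
    """Min/max height summary of a grid-scan table (nm)."""
    return {
        "n_points": int(len(table)),
        "height_min_nm": float(table["height_nm"].min()),
        "height_max_nm": float(table["height_nm"].max()),
    }
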