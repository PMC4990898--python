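"""Inter-dimer electrostatic interaction energies over snapshot ensembles.

The headline quantity is the solvent-screened electrostatic interaction
energy between two tubulin heterodimers forming a tetramer interface,
computed per snapshot by the subtraction scheme

    E_int = E(tetramer) - E(dimer 1) - E(dimer 2)

evaluated separately for the Coulombic term and the electrostatic
solvation term, and summed.  Solvation is a Still-type pairwise
generalized-Born model with HCT-style (pairwise descreening) effective
Born radii — an analytic stand-in with the same decomposition structure as
grid-based GB models, not a reimplementation of any particular one.  The
nonpolar (surface-area) term is computed and reported separately; it is
not part of the headline electrostatic sum.

Snapshots are generated by restrained thermal sampling: harmonic
positional restraints (1 kcal/mol/A^2 by default) on all backbone atoms,
plus a soft-sphere overlap repulsion, integrated with the Langevin
thermostat of the restraint engine.

Energies in kcal/mol, lengths in A, charges in elementary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .restraints import (
    EngineState,
    Restraint,
    RestraintSet,
    dynamics_nvt,
)
from .structure import AtomicStructure, StructureError

__all__ = [
    "ESModel",
    "SamplerSpec",
    "EnergyReport",
    "PooledSummary",
    "SnapshotPlan",
    "coulomb_energy",
    "born_radii",
    "gb_solvation_energy",
    "shrake_rupley_sasa",
    "nonpolar_energy",
    "interaction_energy",
    "interaction_energy_ensemble",
    "sample_restrained_snapshots",
    "snapshot_plan",
    "pool_statistics",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0636  # kcal A / (mol e^2)


class EnergyError(ValueError):
    pass


@dataclass(frozen=True)
class ESModel:
    """Electrostatic model parameters.

    Solute dielectric 1, solvent dielectric 80, infinite cutoff; nonpolar
    surface tension 0.03 kcal/mol/A^2 with a 1.4 A probe.  The descreening
    scale applies to neighbor radii in the Born-radius integral.
    """

    eps_solute: float = 1.0
    eps_solvent: float = 80.0
    k_coulomb: float = COULOMB_CONSTANT
    surface_tension: float = 0.03
    probe_radius: float = 1.4
    sasa_points: int = 960
    descreen_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.eps_solute < 1 or self.eps_solvent < 1:
            raise EnergyError("dielectric constants must be >= 1")
        if self.surface_tension < 0:
            raise EnergyError("surface tension must be >= 0")


def _require_charges(structure: AtomicStructure) -> np.ndarray:
    if structure.charges is None:
        raise EnergyError("structure has no partial charges")
    return structure.charges


def _require_radii(structure: AtomicStructure) -> np.ndarray:
    if structure.radii is None:
        raise EnergyError("structure has no intrinsic radii")
    return structure.radii


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def coulomb_energy(
    structure: AtomicStructure, model: ESModel | None = None
) -> float:
    """Total Coulomb energy, sum over all pairs of k q_i q_j / (eps_in r),
    with no distance cutoff."""
    if model is None:
        model = ESModel()
    q = _require_charges(structure)
    n = len(structure)
    if n < 2:
        return 0.0
    r = _pair_distances(structure.coords)
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    qq = (q[:, None] * q[None, :])[iu]
    if np.any((rij < 1e-6) & (np.abs(qq) > 0)):
        raise EnergyError("coincident charged atoms")
    return float(model.k_coulomb / model.eps_solute * np.sum(qq / rij))


def born_radii(
    structure: AtomicStructure, model: ESModel | None = None
) -> np.ndarray:
    """Effective Born radii via pairwise descreening.

    Each atom's inverse Born radius starts at the inverse intrinsic radius
    and is reduced by the descreening integral over every neighbor sphere
    (neighbor radii scaled by ``descreen_scale``).  An isolated atom's
    Born radius equals its intrinsic radius exactly.
    """
    if model is None:
        model = ESModel()
    rho = _require_radii(structure)
    n = len(structure)
    if np.any(rho <= 0):
        raise EnergyError("intrinsic radii must be positive")
    if n == 1:
        return rho.copy()
    r = _pair_distances(structure.coords)
    s_rho = model.descreen_scale * rho
    inv_b = 1.0 / rho
    for i in range(n):
        rij = r[i]
        sj = s_rho.copy()
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask &= rho[i] < rij + sj  # neighbor shell reaches past rho_i
        if not np.any(mask):
            continue
        rij = rij[mask]
        sj = sj[mask]
        u = rij + sj
        low = np.maximum(rho[i], np.abs(rij - sj))
        term = (
            1.0 / low
            - 1.0 / u
            + (rij / 4.0) * (1.0 / u**2 - 1.0 / low**2)
            + (1.0 / (2.0 * rij)) * np.log(low / u)
            + (sj**2 / (4.0 * rij)) * (1.0 / low**2 - 1.0 / u**2)
        )
        inv_b[i] -= 0.5 * float(np.sum(term))
    # descreening cannot push an inverse radius negative in practice;
    # guard against pathological overlap anyway
    inv_b = np.maximum(inv_b, 1e-6)
    return 1.0 / inv_b


def gb_solvation_energy(
    structure: AtomicStructure, model: ESModel | None = None
) -> float:
    """Generalized-Born electrostatic solvation free energy.

    Still's interpolation: Delta G = -1/2 (1/eps_in - 1/eps_out) k
    sum_ij q_i q_j / f_GB with f_GB = sqrt(r^2 + B_i B_j exp(-r^2 /
    (4 B_i B_j))); the i = j terms are the Born self-energies.
    """
    if model is None:
        model = ESModel()
    q = _require_charges(structure)
    if np.all(q == 0):
        return 0.0
    b = born_radii(structure, model)
    r2 = _pair_distances(structure.coords) ** 2
    bb = b[:, None] * b[None, :]
    f = np.sqrt(r2 + bb * np.exp(-r2 / (4.0 * bb)))
    pref = -0.5 * (1.0 / model.eps_solute - 1.0 / model.eps_solvent)
    return float(pref * model.k_coulomb *
                 np.sum((q[:, None] * q[None, :]) / f))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi),
         np.cos(phi))
    )


def shrake_rupley_sasa(
    structure: AtomicStructure, model: ESModel | None = None
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Deterministic Shrake-Rupley: a fixed golden-spiral point set (960
    points per atom by default) on each solvent-extended sphere; points
    inside any other extended sphere are buried.
    """
    if model is None:
        model = ESModel()
    rho = _require_radii(structure)
    coords = structure.coords
    n = len(structure)
    ext = rho + model.probe_radius
    pts = _sphere_points(model.sasa_points)
    r = _pair_distances(coords)
    out = np.zeros(n)
    for i in range(n):
        neighbors = np.flatnonzero(
            (r[i] < ext[i] + ext) & (np.arange(n) != i)
        )
        surface = coords[i] + ext[i] * pts
        if len(neighbors):
            diff = surface[:, None, :] - coords[neighbors][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = np.any(d2 < (ext[neighbors] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return out


def nonpolar_energy(
    structure: AtomicStructure, model: ESModel | None = None
) -> float:
    """Nonpolar solvation term: surface tension times total SASA."""
    if model is None:
        model = ESModel()
    return float(model.surface_tension *
                 shrake_rupley_sasa(structure, model).sum())


@dataclass(frozen=True)
class EnergyReport:
    """Single-snapshot interaction energy decomposition (kcal/mol)."""

    e_coul_tetramer: float
    e_coul_dimer1: float
    e_coul_dimer2: float
    e_solv_tetramer: float
    e_solv_dimer1: float
    e_solv_dimer2: float
    e_np_tetramer: float
    e_np_dimer1: float
    e_np_dimer2: float

    @property
    def e_coul_int(self) -> float:
        return self.e_coul_tetramer - self.e_coul_dimer1 - self.e_coul_dimer2

    @property
    def e_solv_int(self) -> float:
        return self.e_solv_tetramer - self.e_solv_dimer1 - self.e_solv_dimer2

    @property
    def e_np_int(self) -> float:
        return self.e_np_tetramer - self.e_np_dimer1 - self.e_np_dimer2

    @property
    def e_total_int(self) -> float:
        """Headline electrostatic interaction: Coulomb + solvation."""
        return self.e_coul_int + self.e_solv_int

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in self.__dataclass_fields__.values()
        }
        d.update(
            e_coul_int=self.e_coul_int,
            e_solv_int=self.e_solv_int,
            e_np_int=self.e_np_int,
            e_total_int=self.e_total_int,
        )
        return d


def interaction_energy(
    tetramer: AtomicStructure,
    sel1,
    sel2,
    model: ESModel | None = None,
    include_nonpolar: bool = True,
) -> EnergyReport:
    """Dimer-dimer interaction terms by the subtraction scheme.

    ``sel1``/``sel2`` are boolean masks (or chain-id collections) that must
    be disjoint and cover the tetramer.  All terms are evaluated on the
    same coordinates; the total electrostatic interaction is exactly the
    sum of the Coulombic and solvation interaction terms, while the
    nonpolar (gamma * SASA) subtraction is reported separately.
    """
    if model is None:
        model = ESModel()
    m1 = _as_mask(tetramer, sel1)
    m2 = _as_mask(tetramer, sel2)
    if np.any(m1 & m2):
        raise EnergyError("dimer selections overlap")
    if not np.all(m1 | m2):
        raise EnergyError("dimer selections must cover the tetramer")
    d1 = tetramer.select(m1)
    d2 = tetramer.select(m2)
    e_np = (0.0, 0.0, 0.0)
    if include_nonpolar:
        e_np = (
            nonpolar_energy(tetramer, model),
            nonpolar_energy(d1, model),
            nonpolar_energy(d2, model),
        )
    return EnergyReport(
        e_coul_tetramer=coulomb_energy(tetramer, model),
        e_coul_dimer1=coulomb_energy(d1, model),
        e_coul_dimer2=coulomb_energy(d2, model),
        e_solv_tetramer=gb_solvation_energy(tetramer, model),
        e_solv_dimer1=gb_solvation_energy(d1, model),
        e_solv_dimer2=gb_solvation_energy(d2, model),
        e_np_tetramer=e_np[0],
        e_np_dimer1=e_np[1],
        e_np_dimer2=e_np[2],
    )


def _as_mask(structure: AtomicStructure, sel) -> np.ndarray:
    """Boolean mask from either a mask array or a chain-id collection."""
    if isinstance(sel, np.ndarray) and sel.dtype == bool:
        if sel.shape != (len(structure),):
            raise EnergyError("selection mask has wrong length")
        return sel
    return structure.chain_mask(sel)


def interaction_energy_ensemble(
    snapshots,
    sel1,
    sel2,
    model: ESModel | None = None,
    include_nonpolar: bool = True,
    replica: int | None = None,
) -> pd.DataFrame:
    """Per-snapshot interaction energy table for an ordered snapshot set."""
    rows = []
    for i, snap in enumerate(snapshots):
        rep = interaction_energy(snap, sel1, sel2, model,
                                 include_nonpolar=include_nonpolar)
        row = {"snapshot": i}
        if replica is not None:
            row["replica"] = replica
        row.update(rep.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# -- restrained snapshot sampling ----------------------------------------


@dataclass(frozen=True)
class SamplerSpec:
    """Restrained-ensemble sampler parameters.

    Positional restraints of force constant ``k`` (kcal/mol/A^2) tether
    the selected (backbone, by default) atoms to their input coordinates;
    snapshots are saved every ``stride`` steps after ``equilibration``
    discarded steps.
    """

    k: float = 1.0
    temperature: float = 300.0
    n_snapshots: int = 100
    stride: int = 10
    equilibration: int = 100
    dt: float = 0.002
    seed: int = 0
    selector: str = "backbone"
    k_repulsion: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise EnergyError("restraint k must be >= 0")
        if min(self.n_snapshots, self.stride) < 1 or self.equilibration < 0:
            raise EnergyError("counts must be positive")


def _soft_sphere(radii: np.ndarray, k_rep: float):
    """Soft-sphere overlap repulsion E = k (sigma_ij - r)^2 for r < sigma."""
    sigma = radii[:, None] + radii[None, :]

    def potential(coords: np.ndarray):
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(r, np.inf)
        overlap = np.maximum(sigma - r, 0.0)
        e = 0.5 * k_rep * float(np.sum(overlap**2))
        with np.errstate(invalid="ignore"):
            scale = np.where(overlap > 0, -2.0 * k_rep * overlap / r, 0.0)
        grad = np.einsum("ij,ijk->ik", scale, diff)
        return e, grad

    return potential


def sample_restrained_snapshots(
    structure: AtomicStructure, sampler: SamplerSpec
) -> list:
    """Thermal snapshot ensemble about a reference structure.

    The potential is restraints-only (positional tethers on the selected
    atoms) plus the soft-sphere repulsion; the Langevin thermostat supplies
    the heat bath.  Returns exactly ``n_snapshots`` structures; identical
    seeds give identical ensembles.
    """
    if sampler.selector == "backbone":
        selected = np.flatnonzero(structure.backbone)
    elif sampler.selector == "all":
        selected = np.arange(len(structure))
    else:
        raise EnergyError(f"unknown selector {sampler.selector!r}")
    if len(selected) == 0:
        raise EnergyError("restraint selection matches no atoms")
    rs = RestraintSet(
        Restraint("positional", (int(i),), structure.coords[i], sampler.k,
                  label="tether")
        for i in selected
    )
    extra = None
    if sampler.k_repulsion > 0 and structure.radii is not None:
        extra = _soft_sphere(structure.radii, sampler.k_repulsion)
    masses = np.full(len(structure), 12.0)
    state = EngineState(coords=structure.coords.copy(), masses=masses)

    snapshots: list[AtomicStructure] = []

    def keep(step: int, coords: np.ndarray) -> None:
        if step > sampler.equilibration and len(snapshots) < (
            sampler.n_snapshots
        ):
            snapshots.append(structure.with_coords(coords))

    total = sampler.equilibration + sampler.stride * sampler.n_snapshots
    dynamics_nvt(
        state,
        rs,
        n_steps=total,
        temperature=sampler.temperature,
        dt=sampler.dt,
        seed=sampler.seed,
        extra_potential=extra,
        sample_every=sampler.stride,
        sample_callback=keep,
    )
    if len(snapshots) != sampler.n_snapshots:
        raise EnergyError("sampler produced a short ensemble")
    return snapshots


@dataclass(frozen=True)
class SnapshotPlan:
    per_replica: int
    per_system: int
    total_simulations: int


def snapshot_plan(
    sim_length_ps: float = 1000.0,
    save_ps: float = 1.0,
    equil_ps: float = 10.0,
    replicas: int = 5,
    systems: int = 4,
) -> SnapshotPlan:
    """Ensemble bookkeeping: snapshots per replica = (length - equil) /
    save interval; per tetramer system = that times the replica count."""
    if equil_ps >= sim_length_ps:
        raise EnergyError("equilibration must be shorter than the run")
    span = sim_length_ps - equil_ps
    per = span / save_ps
    if abs(per - round(per)) > 1e-9:
        raise EnergyError("save interval does not divide the sampled span")
    per = int(round(per))
    return SnapshotPlan(
        per_replica=per,
        per_system=per * replicas,
        total_simulations=replicas * systems,
    )


@dataclass(frozen=True)
class PooledSummary:
    """Per-replica and pooled mean/SD (sample SD, n-1 denominator)."""

    replica_means: tuple
    replica_sds: tuple
    replica_ns: tuple
    pooled_mean: float
    pooled_sd: float
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"replica_{i + 1}": [m, s]
            for i, (m, s) in enumerate(
                zip(self.replica_means, self.replica_sds)
            )
        }
        cols["pooled"] = [self.pooled_mean, self.pooled_sd]
        return pd.DataFrame(cols, index=["mean", "sd"])


def pool_statistics(replica_values) -> PooledSummary:
    """Summarize per-replica value sets the way ensemble tables are
    reported: a mean and sample SD per replica, plus the mean and sample
    SD of all values pooled together."""
    groups = [np.asarray(v, dtype=float) for v in replica_values]
    if not groups or any(len(g) == 0 for g in groups):
        raise EnergyError("every replica must contain at least one value")
    means = tuple(float(g.mean()) for g in groups)
    sds = tuple(
        float(g.std(ddof=1)) if len(g) > 1 else 0.0 for g in groups
    )
    pooled = np.concatenate(groups)
    return PooledSummary(
        replica_means=means,
        replica_sds=sds,
        replica_ns=tuple(len(g) for g in groups),
        pooled_mean=float(pooled.mean()),
        pooled_sd=float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
        n_total=int(len(pooled)),
    )
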