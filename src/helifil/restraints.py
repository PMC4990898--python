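"""Harmonic restraint energies, steepest-descent minimization, NVT dynamics.

The energy convention is E = k * delta^2 (no factor of one half), matching
the way restraint force constants are conventionally printed in kcal/mol/A^2
by molecular mechanics packages.  All equilibrium-variance formulas used in
tests therefore carry an effective spring constant of 2k:
<dx^2> = kB*T / (2k) per restrained degree of freedom.

Units: lengths A, energies kcal/mol, masses amu, time ps.  With those
choices 1 kcal/mol = 418.4 amu A^2/ps^2 and kB = 0.0019872041 kcal/mol/K.

Restraint kinds and member arity:

==============  =====  =======================================
kind            arity  deviation delta
==============  =====  =======================================
``distance``    2      |r_i - r_j| - d0
``angle``       3      theta(i,j,k) - theta0     (radians)
``torsion``     4      wrap(phi(i,j,k,l) - phi0) (radians)
``cylindrical`` 1      hypot(x, y) - rho0  (distance from z axis)
``positional``  1      |r - r0|   (3D tether to a fixed point)
==============  =====  =======================================

Angle and torsion targets are supplied in degrees and their force constants
in kcal/mol/rad^2; torsion deviations use the minimum-image angular
difference in (-180, 180] degrees to avoid the periodic discontinuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Restraint",
    "RestraintSet",
    "EngineState",
    "MinimizeStage",
    "DynamicsStage",
    "ProtocolSpec",
    "restraint_energy",
    "minimize_sd",
    "minimize_lbfgs",
    "dynamics_nvt",
    "run_protocol",
    "sd_nvt_sd",
    "sd_nvt_qn",
    "KB",
    "KCAL_TO_AKMA",
]

KB = 0.0019872041  # kcal/mol/K
KCAL_TO_AKMA = 418.4  # 1 kcal/mol in amu A^2 / ps^2

_ARITY = {
    "distance": 2,
    "angle": 3,
    "torsion": 4,
    "cylindrical": 1,
    "positional": 1,
}


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class Restraint:
    """A single typed harmonic restraint.

    ``target`` is a length in A (distance/cylindrical), an angle in degrees
    (angle/torsion), or a 3-vector in A (positional).  ``label`` is free-form
    bookkeeping used by the lattice builders (e.g. "lateral", "longitudinal").
    """

    kind: str
    members: tuple[int, ...]
    target: object
    k: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _ARITY:
            raise RestraintError(f"unknown restraint kind {self.kind!r}")
        members = tuple(int(m) for m in self.members)
        object.__setattr__(self, "members", members)
        if len(members) != _ARITY[self.kind]:
            raise RestraintError(
                f"{self.kind} restraint needs {_ARITY[self.kind]} members, "
                f"got {len(members)}"
            )
        if len(set(members)) != len(members):
            raise RestraintError("restraint members must be distinct")
        if self.k < 0:
            raise RestraintError("force constant must be >= 0")
        if self.kind == "positional":
            t = np.asarray(self.target, dtype=float)
            if t.shape != (3,):
                raise RestraintError("positional target must be a 3-vector")
            object.__setattr__(self, "target", t)
        else:
            object.__setattr__(self, "target", float(self.target))

    def to_dict(self) -> dict:
        t = self.target
        return {
            "kind": self.kind,
            "members": list(self.members),
            "target": t.tolist() if isinstance(t, np.ndarray) else t,
            "k": self.k,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Restraint":
        return cls(
            kind=d["kind"],
            members=tuple(d["members"]),
            target=d["target"],
            k=d["k"],
            label=d.get("label", ""),
        )


class RestraintSet:
    """A mutable collection of restraints with vectorized evaluation."""

    def __init__(self, restraints: Iterable[Restraint] = ()):  # noqa: D107
        self._restraints: list[Restraint] = list(restraints)
        self._compiled = None

    def __len__(self) -> int:
        return len(self._restraints)

    def __iter__(self):
        return iter(self._restraints)

    def add(self, restraint: Restraint) -> None:
        self._restraints.append(restraint)
        self._compiled = None

    def extend(self, restraints: Iterable[Restraint]) -> None:
        self._restraints.extend(restraints)
        self._compiled = None

    def filtered(self, pred: Callable[[Restraint], bool]) -> "RestraintSet":
        return RestraintSet(r for r in self._restraints if pred(r))

    def by_label(self, label: str) -> list[Restraint]:
        return [r for r in self._restraints if r.label == label]

    def labels(self) -> set[str]:
        return {r.label for r in self._restraints}

    def to_json_obj(self) -> list[dict]:
        return [r.to_dict() for r in self._restraints]

    @classmethod
    def from_json_obj(cls, obj: Sequence[dict]) -> "RestraintSet":
        return cls(Restraint.from_dict(d) for d in obj)

    # -- vectorized evaluation -------------------------------------------

    def _compile(self):
        if self._compiled is None:
            groups: dict[str, dict] = {}
            for kind in _ARITY:
                rs = [r for r in self._restraints if r.kind == kind]
                if not rs:
                    continue
                idx = np.array([r.members for r in rs], dtype=int)
                k = np.array([r.k for r in rs])
                if kind == "positional":
                    tgt = np.array([r.target for r in rs])
                elif kind in ("angle", "torsion"):
                    tgt = np.deg2rad([r.target for r in rs])
                else:
                    tgt = np.array([r.target for r in rs])
                groups[kind] = {"idx": idx, "k": k, "target": tgt}
            self._compiled = groups
        return self._compiled

    def energy_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return restraint_energy(coords, self)


def _angle_terms(coords, idx, k, theta0):
    ri, rj, rk = (coords[idx[:, c]] for c in range(3))
    u = ri - rj
    v = rk - rj
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cos = np.clip(cos, -1.0, 1.0)
    theta = np.arccos(cos)
    delta = theta - theta0
    e = float(np.sum(k * delta * delta))
    sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-12, None))
    uhat = u / nu[:, None]
    vhat = v / nv[:, None]
    dthe_dri = (cos[:, None] * uhat - vhat) / (nu * sin)[:, None]
    dthe_drk = (cos[:, None] * vhat - uhat) / (nv * sin)[:, None]
    pre = (2.0 * k * delta)[:, None]
    gi = pre * dthe_dri
    gk = pre * dthe_drk
    gj = -(gi + gk)
    return e, ((idx[:, 0], gi), (idx[:, 1], gj), (idx[:, 2], gk))


def _torsion_terms(coords, idx, k, phi0):
    ri, rj, rk, rl = (coords[idx[:, c]] for c in range(4))
    b1 = rj - ri
    b2 = rk - rj
    b3 = rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    # minimum-image angular difference in (-pi, pi]
    delta = phi - phi0
    delta = delta - 2.0 * np.pi * np.floor((delta + np.pi) / (2.0 * np.pi))
    e = float(np.sum(k * delta * delta))
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # signs match the atan2(m1.n2, n1.n2) convention used above
    dphi_dri = (nb2 / n1sq)[:, None] * n1
    dphi_drl = -(nb2 / n2sq)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2))[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2))[:, None]
    dphi_drj = -(1.0 + s12) * dphi_dri + s32 * dphi_drl
    dphi_drk = s12 * dphi_dri - (1.0 + s32) * dphi_drl
    pre = (2.0 * k * delta)[:, None]
    return e, (
        (idx[:, 0], pre * dphi_dri),
        (idx[:, 1], pre * dphi_drj),
        (idx[:, 2], pre * dphi_drk),
        (idx[:, 3], pre * dphi_drl),
    )


def restraint_energy(
    coords: np.ndarray, restraints: RestraintSet
) -> tuple[float, np.ndarray]:
    """Total restraint energy (kcal/mol) and its analytic gradient.

    The gradient has the same shape as ``coords``; forces are its negative.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    grad = np.zeros_like(coords)
    energy = 0.0
    groups = restraints._compile()

    for kind, g in groups.items():
        idx, k, tgt = g["idx"], g["k"], g["target"]
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            bad = idx[(idx < 0) | (idx >= n)][0]
            raise RestraintError(
                f"{kind} restraint refers to missing particle id {bad}"
            )
        if kind == "distance":
            d = coords[idx[:, 0]] - coords[idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            delta = r - tgt
            energy += float(np.sum(k * delta * delta))
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(r[:, None] > 0, d / r[:, None], 0.0)
            gpair = (2.0 * k * delta)[:, None] * unit
            np.add.at(grad, idx[:, 0], gpair)
            np.add.at(grad, idx[:, 1], -gpair)
        elif kind == "positional":
            d = coords[idx[:, 0]] - tgt
            energy += float(np.sum(k * np.einsum("ij,ij->i", d, d)))
            np.add.at(grad, idx[:, 0], 2.0 * k[:, None] * d)
        elif kind == "cylindrical":
            xy = coords[idx[:, 0], :2]
            rho = np.linalg.norm(xy, axis=1)
            delta = rho - tgt
            energy += float(np.sum(k * delta * delta))
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(rho[:, None] > 0, xy / rho[:, None], 0.0)
            gxy = (2.0 * k * delta)[:, None] * unit
            g3 = np.zeros((len(idx), 3))
            g3[:, :2] = gxy
            np.add.at(grad, idx[:, 0], g3)
        elif kind == "angle":
            e, contribs = _angle_terms(coords, idx, k, tgt)
            energy += e
            for ids, gc in contribs:
                np.add.at(grad, ids, gc)
        elif kind == "torsion":
            e, contribs = _torsion_terms(coords, idx, k, tgt)
            energy += e
            for ids, gc in contribs:
                np.add.at(grad, ids, gc)
    if not np.isfinite(energy):
        raise RestraintError("non-finite restraint energy")
    return energy, grad


# -- engine state and protocols ------------------------------------------


@dataclass
class EngineState:
    """Coordinates, velocities and bookkeeping for the optimizer/integrator."""

    coords: np.ndarray
    masses: np.ndarray
    velocities: np.ndarray | None = None
    step: int = 0
    energy_trace: list = field(default_factory=list)
    termination: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise RestraintError("non-finite coordinates")
        if self.masses.shape != (len(self.coords),):
            raise RestraintError("masses must have one entry per particle")

    @classmethod
    def from_model(cls, model) -> "EngineState":
        return cls(coords=model.positions.copy(), masses=model.masses.copy())

    def copy(self) -> "EngineState":
        return replace(
            self,
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            energy_trace=list(self.energy_trace),
        )


@dataclass(frozen=True)
class MinimizeStage:
    max_steps: int = 2000
    tol: float = 0.001  # kcal/mol energy-change tolerance
    method: str = "sd"  # "sd" (steepest descent) or "lbfgs" (quasi-Newton)

    def __post_init__(self):
        if self.max_steps <= 0:
            raise RestraintError("max_steps must be > 0")
        if self.tol <= 0:
            raise RestraintError("tol must be > 0")
        if self.method not in ("sd", "lbfgs"):
            raise RestraintError(f"unknown minimizer {self.method!r}")


@dataclass(frozen=True)
class DynamicsStage:
    n_steps: int = 1000
    temperature: float = 100.0  # Kelvin
    dt: float = 0.002  # ps
    seed: int | None = None
    friction: float = 1.0  # 1/ps

    def __post_init__(self):
        if self.n_steps <= 0:
            raise RestraintError("n_steps must be > 0")
        if self.temperature < 0:
            raise RestraintError("temperature must be >= 0")
        if self.dt <= 0:
            raise RestraintError("dt must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered sequence of minimization and dynamics stages."""

    stages: tuple = ()

    def with_seed(self, seed: int) -> "ProtocolSpec":
        """Return a copy whose dynamics stages carry derived seeds."""
        out = []
        for i, st in enumerate(self.stages):
            if isinstance(st, DynamicsStage) and st.seed is None:
                st = replace(st, seed=int(seed) + i)
            out.append(st)
        return ProtocolSpec(stages=tuple(out))


def sd_nvt_sd(
    seed: int | None = None,
    sd_steps: int = 2000,
    nvt_steps: int = 1000,
    temperature: float = 100.0,
    tol: float = 0.001,
    dt: float = 0.002,
) -> ProtocolSpec:
    """The canonical three-stage optimization protocol:

    (a) steepest-descent minimization to an energy-change tolerance,
    (b) constant-volume, constant-temperature dynamics at 100 K,
    (c) a second steepest-descent minimization.
    """
    proto = ProtocolSpec(
        stages=(
            MinimizeStage(max_steps=sd_steps, tol=tol),
            DynamicsStage(n_steps=nvt_steps, temperature=temperature, dt=dt),
            MinimizeStage(max_steps=sd_steps, tol=tol),
        )
    )
    return proto if seed is None else proto.with_seed(seed)


def sd_nvt_qn(
    seed: int | None = None,
    sd_steps: int = 2000,
    nvt_steps: int = 1000,
    temperature: float = 100.0,
    qn_steps: int = 30000,
    dt: float = 0.002,
) -> ProtocolSpec:
    """Model-building protocol: steepest descent, NVT dynamics at 100 K,
    then a quasi-Newton polish for the ill-conditioned collective modes."""
    proto = ProtocolSpec(
        stages=(
            MinimizeStage(max_steps=sd_steps, tol=0.001, method="sd"),
            DynamicsStage(n_steps=nvt_steps, temperature=temperature, dt=dt),
            MinimizeStage(max_steps=qn_steps, tol=1e-14, method="lbfgs"),
        )
    )
    return proto if seed is None else proto.with_seed(seed)


ExtraPotential = Callable[[np.ndarray], tuple[float, np.ndarray]]


def _total_energy(coords, restraints, extra):
    e, g = restraint_energy(coords, restraints)
    if extra is not None:
        ee, ge = extra(coords)
        e += ee
        g = g + ge
    return e, g


def minimize_sd(
    state: EngineState,
    restraints: RestraintSet,
    max_steps: int = 2000,
    tol: float = 0.001,
    extra_potential: ExtraPotential | None = None,
    initial_step: float = 0.1,
    max_step: float = 1.0,
) -> EngineState:
    """Adaptive-step steepest descent.

    The trial displacement scales the negative gradient so the largest
    per-particle move equals the current trust radius (0.1 A initially);
    rejected uphill moves halve the radius, accepted moves grow it by 20%
    up to ``max_step``.  Terminates when the energy change between accepted
    steps falls below ``tol`` (kcal/mol) or after ``max_steps`` steps.
    Energy never increases between accepted steps.
    """
    if tol <= 0:
        raise RestraintError("tol must be > 0")
    state = state.copy()
    coords = state.coords
    e, g = _total_energy(coords, restraints, extra_potential)
    state.energy_trace.append(e)
    trust = float(initial_step)
    reason = "max_steps"
    for _ in range(max_steps):
        gmax = float(np.max(np.linalg.norm(g, axis=1)))
        if gmax == 0.0:
            reason = "zero_gradient"
            break
        accepted = False
        while trust > 1e-12:
            trial = coords - g * (trust / gmax)
            et, gt = _total_energy(trial, restraints, extra_potential)
            if et <= e:
                accepted = True
                break
            trust *= 0.5
        if not accepted:
            reason = "line_search_stalled"
            break
        de = e - et
        coords, e, g = trial, et, gt
        state.energy_trace.append(e)
        state.step += 1
        trust = min(trust * 1.2, max_step)
        if de < tol:
            reason = "converged"
            break
    state.coords = coords
    state.termination = reason
    return state


def minimize_lbfgs(
    state: EngineState,
    restraints: RestraintSet,
    max_steps: int = 20000,
    tol: float = 1e-10,
    extra_potential: ExtraPotential | None = None,
) -> EngineState:
    """Quasi-Newton (L-BFGS) minimization.

    Used as the polish stage of the model-building protocols, where the
    collective re-winding modes of the filament are far too ill-conditioned
    for plain steepest descent.  ``tol`` maps to the relative
    energy-decrease stopping criterion.
    """
    from scipy.optimize import minimize as _scipy_minimize

    state = state.copy()
    shape = state.coords.shape

    def fg(x):
        e, g = _total_energy(x.reshape(shape), restraints, extra_potential)
        return e, g.ravel()

    e0, _ = fg(state.coords.ravel())
    state.energy_trace.append(e0)
    res = _scipy_minimize(
        fg,
        state.coords.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "ftol": tol, "gtol": 1e-10},
    )
    state.coords = res.x.reshape(shape)
    state.energy_trace.append(float(res.fun))
    state.step += int(res.nit)
    state.termination = "converged" if res.success else str(res.message)
    return state


def dynamics_nvt(
    state: EngineState,
    restraints: RestraintSet,
    n_steps: int = 1000,
    temperature: float = 100.0,
    dt: float = 0.002,
    seed: int | None = None,
    friction: float = 1.0,
    extra_potential: ExtraPotential | None = None,
    sample_every: int = 0,
    sample_callback: Callable[[int, np.ndarray], None] | None = None,
) -> EngineState:
    """Leapfrog Langevin (BAOAB-split) constant-T dynamics.

    Bit-identical trajectories for identical seeds.  The long-run mean
    kinetic energy per degree of freedom converges to kB*T/2 and the
    positional variance of a k-restrained coordinate to kB*T/(2k).
    """
    if dt <= 0:
        raise RestraintError("dt must be > 0")
    if seed is None:
        raise RestraintError("dynamics requires an explicit seed")
    state = state.copy()
    rng = np.random.default_rng(int(seed))
    x = state.coords
    m = state.masses[:, None]
    kt = KB * temperature * KCAL_TO_AKMA  # amu A^2/ps^2
    if state.velocities is None:
        v = rng.normal(size=x.shape) * np.sqrt(kt / m)
    else:
        v = state.velocities.copy()

    e, g = _total_energy(x, restraints, extra_potential)
    state.energy_trace.append(e)
    f = -g * KCAL_TO_AKMA  # amu A/ps^2
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    half = 0.5 * dt
    ke_accum = 0.0
    for i in range(n_steps):
        v = v + half * f / m
        x = x + half * v
        v = c1 * v + c2 * np.sqrt(kt / m) * rng.normal(size=x.shape)
        x = x + half * v
        e, g = _total_energy(x, restraints, extra_potential)
        f = -g * KCAL_TO_AKMA
        v = v + half * f / m
        ke_accum += 0.5 * float(np.sum(m * v * v)) / KCAL_TO_AKMA
        state.step += 1
        if sample_callback is not None and sample_every > 0:
            if (i + 1) % sample_every == 0:
                sample_callback(i + 1, x.copy())
    state.energy_trace.append(e)
    state.coords = x
    state.velocities = v
    state.mean_kinetic = ke_accum / n_steps  # kcal/mol, diagnostics
    state.termination = "dynamics_complete"
    return state


def run_protocol(
    state: EngineState,
    restraints: RestraintSet,
    protocol: ProtocolSpec,
    extra_potential: ExtraPotential | None = None,
) -> tuple[EngineState, list[dict]]:
    """Execute protocol stages in order; returns the final state and a log
    with one entry per stage (start/end energies and termination reason)."""
    log: list[dict] = []
    for stage in protocol.stages:
        e0, _ = _total_energy(state.coords, restraints, extra_potential)
        if isinstance(stage, MinimizeStage):
            if stage.method == "lbfgs":
                state = minimize_lbfgs(
                    state,
                    restraints,
                    max_steps=stage.max_steps,
                    tol=stage.tol,
                    extra_potential=extra_potential,
                )
            else:
                state = minimize_sd(
                    state,
                    restraints,
                    max_steps=stage.max_steps,
                    tol=stage.tol,
                    extra_potential=extra_potential,
                )
            kind = f"minimize_{stage.method}"
        elif isinstance(stage, DynamicsStage):
            seed = stage.seed if stage.seed is not None else 0
            state = dynamics_nvt(
                state,
                restraints,
                n_steps=stage.n_steps,
                temperature=stage.temperature,
                dt=stage.dt,
                seed=seed,
                friction=stage.friction,
                extra_potential=extra_potential,
            )
            kind = "dynamics"
        else:
            raise RestraintError(f"unknown protocol stage {stage!r}")
        e1, _ = _total_energy(state.coords, restraints, extra_potential)
        log.append(
            {
                "stage": kind,
                "start_energy": e0,
                "end_energy": e1,
                "termination": state.termination,
            }
        )
    return state, log
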