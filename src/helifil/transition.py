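"""The 13-3 microtubule to helical-filament transition.

The transition, performed on the point-mass lattice under harmonic
restraints, has four steps:

1. **Seam rewiring** — the alpha-beta lateral contacts at the seam are
   replaced by regular alpha-alpha and beta-beta lateral contacts between
   the last and first strands, making the lateral bonding a single
   continuous dimer strand wound around the cylinder.
2. **Longitudinal removal** — all inter-dimer longitudinal restraints along
   the former protofilaments are dropped (intra-dimer restraints remain),
   reflecting the loss of longitudinal contacts in the filament.
3. **Cylindrical expansion** — a cylindrical restraint pushes every bead to
   the target filament radius while lateral restraints preserve the contact
   spacing; the strand re-winds and the registry (dimers per turn) grows,
   e.g. from 13 to 21 at the mean filament diameter.
4. **Graded stretching** — first-order longitudinal restraints between
   dimers one turn apart (n, n+m) are ramped from 107 A to the target coil
   separation, with second-order restraints between dimers two turns apart
   (n, n+2m) held at exactly twice the first-order target to keep the
   lengthening uniform along the filament.

Each step is optimized with the canonical SD/NVT/SD protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    ALPHA,
    BETA,
    BeadModel,
    HelixGeometry,
    LatticeError,
    LatticeSpec,
    build_mt_lattice,
    end_to_end_length,
    model_registry,
)
from .restraints import (
    DynamicsStage,
    EngineState,
    MinimizeStage,
    ProtocolSpec,
    Restraint,
    RestraintSet,
    run_protocol,
    sd_nvt_qn,
    sd_nvt_sd,
)

__all__ = [
    "default_lattice_restraints",
    "rewire_seam",
    "remove_longitudinal",
    "expand_cylinder",
    "stretch_to_helix",
    "TransitionSchedule",
    "mt_to_hf_pipeline",
    "measure_helix",
    "lateral_pairs",
]


class TransitionError(ValueError):
    pass


def _alpha_bead(d: int) -> int:
    return 2 * d


def _beta_bead(d: int) -> int:
    return 2 * d + 1


def lateral_pairs(spec: LatticeSpec) -> dict:
    """Enumerate lattice adjacencies by dimer index (d -> strand d % N).

    Returns dict with keys ``lateral`` (non-seam adjacent-strand dimer
    pairs), ``seam`` (last-strand to first-strand pairs) and
    ``longitudinal`` (same-strand, adjacent-level pairs).
    """
    n = spec.n_protofilaments
    nd = spec.n_dimers
    lateral, seam, longitudinal = [], [], []
    for d in range(nd):
        s = d % n
        if s < n - 1 and d + 1 < nd:
            lateral.append((d, d + 1))
        elif s == n - 1 and d + 1 < nd:
            seam.append((d, d + 1))
        if d + n < nd:
            longitudinal.append((d, d + n))
    return {"lateral": lateral, "seam": seam, "longitudinal": longitudinal}


def default_lattice_restraints(
    model: BeadModel,
    spec: LatticeSpec | None = None,
    k_distance: float = 10.0,
    k_angle: float = 100.0,
    include_angles: bool = True,
) -> RestraintSet:
    """Harmonic restraint set that maintains the N-S lattice geometry.

    Restraint minima are measured from the ideal lattice built from
    ``spec`` (the force constants are ad hoc: they only need to hold the
    geometry).  Labels: ``intra`` (alpha-beta within a dimer),
    ``longitudinal`` (beta_n : alpha_{n+N} along a protofilament),
    ``lateral`` (alpha-alpha and beta-beta across adjacent strands) and
    ``seam`` (the alpha-beta contacts across the seam:
    alpha_n : beta_{n+1} and beta_n : alpha_{n+1+N}).

    ``include_angles`` (default) adds lateral angle restraints along
    interior laterally-consecutive alpha-bead and beta-bead triples
    (label ``chain_angle``).  These remove the twist/slide degeneracy of a
    purely distance-restrained shell: without them the lateral chain can
    satisfy every pair distance while shearing levels against each other.
    """
    if spec is None:
        spec = model.spec
    if spec is None:
        raise TransitionError("no lattice spec available for restraints")
    ideal = build_mt_lattice(spec)
    pos = ideal.positions

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(pos[i] - pos[j]))

    adj = lateral_pairs(spec)
    rs = RestraintSet()
    for d in range(spec.n_dimers):
        rs.add(
            Restraint(
                "distance",
                (_alpha_bead(d), _beta_bead(d)),
                spec.monomer_rise,
                k_distance,
                label="intra",
            )
        )
    for d, d2 in adj["longitudinal"]:
        i, j = _beta_bead(d), _alpha_bead(d2)
        rs.add(Restraint("distance", (i, j), dist(i, j), k_distance,
                         label="longitudinal"))
    for d, d2 in adj["lateral"]:
        for bead in (_alpha_bead, _beta_bead):
            i, j = bead(d), bead(d2)
            rs.add(Restraint("distance", (i, j), dist(i, j), k_distance,
                             label="lateral"))
    for d, d2 in adj["seam"]:
        # alpha_n : beta_{n+1}
        i, j = _alpha_bead(d), _beta_bead(d2)
        rs.add(Restraint("distance", (i, j), dist(i, j), k_distance,
                         label="seam"))
        # beta_n : alpha_{n+1+N}
        d3 = d2 + spec.n_protofilaments
        if d3 < spec.n_dimers:
            i, j = _beta_bead(d), _alpha_bead(d3)
            rs.add(Restraint("distance", (i, j), dist(i, j), k_distance,
                             label="seam"))
    if include_angles:
        seam_dimers = {d for pair in adj["seam"] for d in pair}

        def suffix(dimers) -> str:
            # restraints whose members span the seam are tagged so the
            # rewiring step can retarget them to interior chain geometry
            return "_seam13" if seam_dimers.intersection(dimers) else ""

        for d in range(1, spec.n_dimers - 1):
            triple = (d - 1, d, d + 1)
            for bead in (_alpha_bead, _beta_bead):
                i, j, k = (bead(t) for t in triple)
                rs.add(Restraint("angle", (i, j, k),
                                 _angle_deg(pos, i, j, k), k_angle,
                                 label="chain_angle" + suffix(triple)))
        for d in range(1, spec.n_dimers - 2):
            quad = (d - 1, d, d + 1, d + 2)
            for bead in (_alpha_bead, _beta_bead):
                i, j, k, l = (bead(t) for t in quad)
                rs.add(Restraint("torsion", (i, j, k, l),
                                 _torsion_deg(pos, i, j, k, l), k_angle,
                                 label="chain_torsion" + suffix(quad)))
        # dimer-axis alignment: angles between the intra-dimer axis and the
        # lateral link pin the beta chain against sliding tangentially
        # relative to the alpha chain (the heterodimer axis stays parallel
        # to the cylinder axis)
        for d, d2 in adj["lateral"] + adj["seam"]:
            for trip in (
                (_beta_bead(d), _alpha_bead(d), _alpha_bead(d2)),
                (_alpha_bead(d), _beta_bead(d), _beta_bead(d2)),
            ):
                rs.add(Restraint("angle", trip,
                                 _angle_deg(pos, *trip), k_angle,
                                 label="dimer_axis" + suffix((d, d2))))
        # cross-level twist torsions: vertical distance restraints alone
        # leave level-against-level rotation quartically soft; the dihedral
        # across a longitudinal link resists it at first order.  Removed
        # with the other inter-dimer longitudinal restraints.
        for d, d2 in adj["longitudinal"]:
            if d + 1 < spec.n_dimers and d2 + 1 < spec.n_dimers:
                quad = (
                    _alpha_bead(d), _alpha_bead(d + 1),
                    _alpha_bead(d2), _alpha_bead(d2 + 1),
                )
                rs.add(Restraint("torsion", quad,
                                 _torsion_deg(pos, *quad), k_angle,
                                 label="longitudinal_twist"))
    return rs


def _angle_deg(pos: np.ndarray, i: int, j: int, k: int) -> float:
    u = pos[i] - pos[j]
    v = pos[k] - pos[j]
    cos = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _torsion_deg(pos: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def interior_chain_geometry(spec: LatticeSpec) -> dict:
    """Interior lateral-chain geometry of the ideal N-S lattice:
    link distance, chain angle/torsion, and the two dimer-axis angles
    (degrees) between the intra-dimer axis and the lateral link."""
    probe = LatticeSpec(
        n_protofilaments=spec.n_protofilaments,
        start_number=spec.start_number,
        monomer_rise=spec.monomer_rise,
        dimer_repeat=spec.dimer_repeat,
        lattice_diameter=spec.lattice_diameter,
        n_dimers=min(spec.n_dimers, spec.n_protofilaments),
        seam_present=spec.seam_present,
    )
    pos = build_mt_lattice(probe).positions
    a = [_alpha_bead(d) for d in range(4)]
    b = [_beta_bead(d) for d in range(4)]
    return {
        "distance": float(np.linalg.norm(pos[a[0]] - pos[a[1]])),
        "angle": _angle_deg(pos, *a[:3]),
        "torsion": _torsion_deg(pos, *a),
        "axis_ba": _angle_deg(pos, b[0], a[0], a[1]),
        "axis_ab": _angle_deg(pos, a[0], b[0], b[1]),
    }


def _lateral_target(spec: LatticeSpec) -> float:
    """3D distance between regular lateral neighbor beads in the lattice."""
    chord = spec.lattice_diameter * np.sin(np.pi / spec.n_protofilaments)
    return float(np.hypot(chord, spec.rise_per_step))


def rewire_seam(
    restraints: RestraintSet, model: BeadModel, spec: LatticeSpec | None = None
) -> RestraintSet:
    """Replace the seam's alpha-beta lateral contacts with alpha-alpha and
    beta-beta contacts between the last and first strands.

    The new contacts pair dimer n on the last strand with dimer n+1 (the
    first-strand dimer one level up) and take the regular interior lateral
    contact geometry (distance, and chain angles if the set carries them)
    as their targets, so on relaxation the lattice re-winds into a
    continuous dimer helix.  Idempotent.
    """
    if model.seam_present is None:
        raise TransitionError("model carries no seam annotation")
    if spec is None:
        spec = model.spec
    if spec is None:
        raise TransitionError("no lattice spec available")
    kinds = model.kinds
    out = RestraintSet()
    existing_lateral: set[frozenset] = set()
    existing_angles: set[tuple] = set()
    k_lat = 10.0
    k_ang = 100.0
    has_angles = False
    for r in restraints:
        if r.label == "seam":
            k_lat = r.k
            continue  # drop all alpha-beta seam contacts
        if r.label.endswith("_seam13"):
            # seam-spanning angle/torsion restraints with 13-3 targets are
            # replaced below by interior-geometry-targeted ones
            has_angles = True
            k_ang = r.k
            continue
        if r.label == "lateral" and kinds[r.members[0]] != kinds[r.members[1]]:
            continue  # safety: no alpha-beta lateral restraint survives
        if r.label in ("lateral", "lateral_hf_seam"):
            existing_lateral.add(frozenset(r.members))
            k_lat = r.k
        if r.label in ("chain_angle", "chain_angle_seam",
                       "chain_torsion", "chain_torsion_seam",
                       "dimer_axis", "dimer_axis_seam"):
            has_angles = True
            k_ang = r.k
            existing_angles.add(r.members)
        out.add(r)
    geom = interior_chain_geometry(spec)
    target, angle0, torsion0 = geom["distance"], geom["angle"], geom["torsion"]
    seam_dimers = {d for pair in lateral_pairs(spec)["seam"] for d in pair}
    for d, d2 in lateral_pairs(spec)["seam"]:
        for bead in (_alpha_bead, _beta_bead):
            pair = (bead(d), bead(d2))
            if frozenset(pair) in existing_lateral:
                continue
            out.add(Restraint("distance", pair, target, k_lat,
                              label="lateral_hf_seam"))
    if has_angles:
        # seam-spanning chain triples/quadruples, retargeted to interior
        # geometry: this is what drives the re-winding into a continuous
        # uniform helix on relaxation
        for d in range(1, spec.n_dimers - 1):
            triple = (d - 1, d, d + 1)
            if not seam_dimers.intersection(triple):
                continue
            for bead in (_alpha_bead, _beta_bead):
                members = tuple(bead(t) for t in triple)
                if members in existing_angles:
                    continue
                out.add(Restraint("angle", members, angle0, k_ang,
                                  label="chain_angle_seam"))
        for d in range(1, spec.n_dimers - 2):
            quad = (d - 1, d, d + 1, d + 2)
            if not seam_dimers.intersection(quad):
                continue
            for bead in (_alpha_bead, _beta_bead):
                members = tuple(bead(t) for t in quad)
                if members in existing_angles:
                    continue
                out.add(Restraint("torsion", members, torsion0, k_ang,
                                  label="chain_torsion_seam"))
        for d, d2 in lateral_pairs(spec)["seam"]:
            for trip, tgt in (
                ((_beta_bead(d), _alpha_bead(d), _alpha_bead(d2)),
                 geom["axis_ba"]),
                ((_alpha_bead(d), _beta_bead(d), _beta_bead(d2)),
                 geom["axis_ab"]),
            ):
                if trip in existing_angles:
                    continue
                out.add(Restraint("angle", trip, tgt, k_ang,
                                  label="dimer_axis_seam"))
    return out


def remove_longitudinal(
    restraints: RestraintSet, model: BeadModel | None = None
) -> RestraintSet:
    """Drop every inter-dimer longitudinal restraint (distance links and
    the cross-level twist torsions); intra-dimer alpha-beta restraints are
    retained.  Idempotent."""
    return restraints.filtered(
        lambda r: not r.label.startswith("longitudinal")
    )


def expand_cylinder(
    state: EngineState,
    restraints: RestraintSet,
    target_radius: float,
    protocol: ProtocolSpec | None = None,
    k_cyl: float = 10.0,
) -> tuple[EngineState, RestraintSet, list[dict]]:
    """Dilate the lattice to ``target_radius`` under a cylindrical restraint
    on every bead, preserving lateral contact spacing.

    The cylindrical restraints stay in the returned set (the filament is
    assumed to keep a uniform diameter through the later stages).
    """
    if target_radius <= 0:
        raise TransitionError("target_radius must be > 0")
    if protocol is None:
        protocol = sd_nvt_qn(seed=0)
    out = restraints.filtered(lambda r: r.label != "cylindrical")
    for i in range(len(state.coords)):
        out.add(Restraint("cylindrical", (i,), target_radius, k_cyl,
                          label="cylindrical"))
    state, log = run_protocol(state, out, protocol)
    return state, out, log


@dataclass(frozen=True)
class TransitionSchedule:
    """Graded stretch schedule.

    ``first_order_targets`` ramps the one-turn (n, n+m) dimer separation
    (107 A to 193 A for the mean filament); ``second_order_targets`` must be
    exactly twice the first-order targets at every increment (214 A to
    386 A) to keep the lengthening uniform.
    """

    target_radius: float
    first_order_targets: tuple
    second_order_targets: tuple
    k_stretch: float = 10.0

    @classmethod
    def linear(
        cls,
        target_radius: float,
        first_start: float = 107.0,
        first_end: float = 193.0,
        n_increments: int = 10,
        k_stretch: float = 10.0,
    ) -> "TransitionSchedule":
        first = np.linspace(first_start, first_end, n_increments)
        return cls(
            target_radius=target_radius,
            first_order_targets=tuple(float(t) for t in first),
            second_order_targets=tuple(float(2 * t) for t in first),
            k_stretch=k_stretch,
        )

    def validate(self) -> None:
        f = np.asarray(self.first_order_targets)
        s = np.asarray(self.second_order_targets)
        if f.shape != s.shape or len(f) < 1:
            raise TransitionError("schedule target sequences must match")
        if np.any(np.abs(s - 2.0 * f) > 1e-9):
            raise TransitionError(
                "second-order targets must be twice the first-order targets"
            )
        if np.any(np.diff(f) < 0):
            raise TransitionError("targets must be monotone increasing")


def _stretch_restraints(
    n_dimers: int, m: int, target: float, k: float
) -> list[Restraint]:
    out = []
    for order, label in ((1, "stretch1"), (2, "stretch2")):
        gap = order * m
        t = order * target
        for d in range(n_dimers - gap):
            for bead in (_alpha_bead, _beta_bead):
                out.append(
                    Restraint("distance", (bead(d), bead(d + gap)), t, k,
                              label=label)
                )
    return out


def stretch_to_helix(
    state: EngineState,
    restraints: RestraintSet,
    schedule: TransitionSchedule,
    registry: int,
    seed: int = 0,
    protocol_factory=None,
) -> tuple[EngineState, RestraintSet, list[dict]]:
    """Run the graded stretch: per increment, set the (n, n+m) and
    (n, n+2m) distance targets and re-optimize with the SD/NVT/SD protocol.
    """
    schedule.validate()
    if registry < 1:
        raise TransitionError("registry must be known (>= 1)")
    n_dimers = len(state.coords) // 2
    log: list[dict] = []
    rng = np.random.default_rng(int(seed))
    base = restraints.filtered(
        lambda r: r.label not in ("stretch1", "stretch2")
    )
    for i, target in enumerate(schedule.first_order_targets):
        rs = RestraintSet(list(base))
        rs.extend(
            _stretch_restraints(n_dimers, registry, target, schedule.k_stretch)
        )
        if protocol_factory is None:
            proto = sd_nvt_qn(seed=int(rng.integers(0, 2**31 - 1)))
        else:
            proto = protocol_factory(i)
        state, stage_log = run_protocol(state, rs, proto)
        log.append(
            {"increment": i, "first_order_target": target, "stages": stage_log}
        )
        base = rs.filtered(lambda r: r.label not in ("stretch1", "stretch2"))
        restraints = rs
    return state, restraints, log


def measure_helix(
    model: BeadModel, spec: LatticeSpec, registry: int | None = None
) -> HelixGeometry:
    """Measure diameter, coil separation, rise and height from bead
    coordinates (registry geometric unless supplied)."""
    if registry is None:
        registry = model_registry(model)
    com = model.dimer_com()
    diameter = 2.0 * float(np.mean(np.hypot(com[:, 0], com[:, 1])))
    m = registry
    dz = com[m:, 2] - com[:-m, 2]
    coil = float(np.mean(dz))
    return HelixGeometry(
        diameter=diameter,
        coil_separation=coil,
        registry=m,
        rise_per_step=coil / m,
        height=end_to_end_length(model, spec.monomer_rise),
    )


def pair_separations(model: BeadModel, registry: int) -> np.ndarray:
    """Axial separations between dimer COMs one turn (m dimers) apart."""
    com = model.dimer_com()
    return com[registry:, 2] - com[:-registry, 2]


def mt_to_hf_pipeline(
    spec: LatticeSpec,
    em_params: dict,
    seed: int = 0,
    n_increments: int = 10,
    first_start: float = 107.0,
) -> tuple[BeadModel, HelixGeometry]:
    """Full coarse-grained transition from the N-S lattice to the helical
    filament at the given EM-derived diameter and coil separation (A).

    Runs seam rewiring, longitudinal removal, a relaxation, cylindrical
    expansion to the target radius and the graded stretch, each under the
    SD/NVT/SD protocol; deterministic for a given seed.
    """
    for key in ("diameter", "coil_separation"):
        if key not in em_params:
            raise TransitionError(f"em_params missing {key!r}")
    diameter = float(em_params["diameter"])
    coil = float(em_params["coil_separation"])
    if diameter <= 0 or coil <= 0:
        raise TransitionError("diameter and coil_separation must be > 0")

    rng = np.random.default_rng(int(seed))
    seeds = rng.integers(0, 2**31 - 1, size=3)

    model = build_mt_lattice(spec)
    restraints = default_lattice_restraints(model, spec)
    restraints = rewire_seam(restraints, model, spec)
    restraints = remove_longitudinal(restraints, model)

    state = EngineState.from_model(model)
    # short relaxation of the rewired, longitudinally-unbonded lattice
    state, _ = run_protocol(state, restraints, sd_nvt_qn(seed=int(seeds[0])))

    state, restraints, _ = expand_cylinder(
        state, restraints, diameter / 2.0, sd_nvt_qn(seed=int(seeds[1]))
    )
    expanded = model.copy()
    expanded.positions = state.coords.copy()
    m = model_registry(expanded)

    schedule = TransitionSchedule.linear(
        diameter / 2.0, first_start=min(first_start, coil), first_end=coil,
        n_increments=n_increments,
    )
    state, restraints, _ = stretch_to_helix(
        state, restraints, schedule, m, seed=int(seeds[2])
    )
    final = model.copy()
    final.positions = state.coords.copy()
    final.seam_present = False
    return final, measure_helix(final, spec, registry=m)
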