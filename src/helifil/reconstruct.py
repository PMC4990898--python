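"""Atomic-detail reconstruction of helical filaments from bead models.

The workflow mirrors how an atomic filament model is projected out of a
coarse-grained one:

1. translate atomic monomer templates onto their bead (centre-of-mass)
   positions, keeping the monomer axis parallel to the cylinder axis;
2. extract the 10 reference C-alpha atoms per heterodimer (five conserved
   residues in each monomer);
3. rotate each dimer rigidly about its own vertical axis so the reference
   atoms sit at cylindrical radii R_i + R_cyldiff, where R_i is the
   reference atom's radial distance in the 13-3 lattice and R_cyldiff the
   uniform radius increase of the filament (two stages, a soft and a stiff
   force constant, as restrained-optimization schedules do);
4. rebuild the full-atom dimer by least-squares (Kabsch) superposition
   onto the reoriented reference points.

Per-dimer internal geometry is preserved exactly: every operation applied
to a dimer is a rigid transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .lattice import ALPHA, BETA, BeadModel
from .structure import AtomicStructure, StructureError, chain_ids

__all__ = [
    "RigidTransform",
    "ReorientSpec",
    "kabsch_superpose",
    "place_on_beads",
    "extract_reference_points",
    "reorient_about_axis",
    "build_atomic_hf",
    "reference_radii_13_3",
]

#: default conserved reference residues (residue name, residue number)
ALPHA_REFERENCE_RESIDUES = (
    ("ARG", 121), ("LYS", 304), ("VAL", 324), ("PRO", 364), ("ASP", 424),
)
BETA_REFERENCE_RESIDUES = (
    ("PRO", 86), ("VAL", 126), ("GLY", 146), ("PRO", 311), ("PHE", 415),
)


class ReconstructError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ReconstructError("rotation must be 3x3, translation 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ReconstructError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(r)), 1.0, abs_tol=1e-10):
            raise ReconstructError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + (
            self.translation
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class ReorientSpec:
    """Parameters of the cylindrical reorientation.

    ``r_cyldiff`` is the uniform radial offset added to each reference
    atom's 13-3 radius; the two stage force constants (kcal/mol/A^2)
    reproduce the soft-then-stiff optimization schedule.
    """

    alpha_refs: tuple = ALPHA_REFERENCE_RESIDUES
    beta_refs: tuple = BETA_REFERENCE_RESIDUES
    r_cyldiff: float = 0.0
    stage_ks: tuple = (1.0, 900.0)
    reference_radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.alpha_refs) + len(self.beta_refs) != 10:
            raise ReconstructError("exactly 10 reference residues required")
        if self.r_cyldiff < 0:
            raise ReconstructError("r_cyldiff must be >= 0")


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper-rotation transform minimizing the RMSD and the
    minimized RMSD itself.  Mirror images are never produced: the rotation
    determinant is constrained to +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ReconstructError("point sets must have equal shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or len(mobile) < 3:
        raise ReconstructError("need at least 3 points of dimension 3")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    a = mobile - cm
    b = target - ct
    sing = np.linalg.svd(a, compute_uv=False)
    if sing[1] < 1e-8 * max(1.0, sing[0]):
        raise ReconstructError("degenerate (collinear) point set")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transform = RigidTransform(rot, ct - rot @ cm)
    rmsd = float(np.sqrt(np.mean(np.sum(
        (transform.apply(mobile) - target) ** 2, axis=1))))
    return transform, rmsd


def place_on_beads(
    templates: dict,
    model: BeadModel,
    orient_azimuthal: bool = False,
) -> AtomicStructure:
    """Translate monomer templates onto bead positions.

    ``templates`` maps bead kinds (``ALPHA``/``BETA``) to template
    structures whose centre of mass is moved to the bead position; internal
    geometry is preserved exactly (pure translation) and the monomer axis
    stays parallel to z.  With ``orient_azimuthal`` each monomer is first
    rotated about z by its bead's azimuth, producing the properly oriented
    lattice (the way monomers sit in the source 13-3 structure).
    One chain per monomer (A, B, ... then two-letter ids).
    """
    ids = chain_ids(len(model))
    placed = []
    for b in range(len(model)):
        kind = int(model.kinds[b])
        if kind not in templates:
            raise ReconstructError(f"no template for bead kind {kind}")
        t = templates[kind]
        mono = t.translated(-t.com())
        if orient_azimuthal:
            x, y = model.positions[b, 0], model.positions[b, 1]
            phi = math.atan2(y, x)
            c, s = math.cos(phi), math.sin(phi)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            mono = mono.transformed(rot, np.zeros(3))
        mono = mono.translated(model.positions[b])
        mono = mono.relabeled(chain=ids[b], segment=int(model.dimer_index[b]))
        placed.append(mono)
    return AtomicStructure.concat(placed)


def extract_reference_points(
    structure: AtomicStructure, spec: ReorientSpec
) -> tuple[np.ndarray, list]:
    """Reference C-alpha coordinates per dimer, in fixed residue order.

    Returns an (n_dimers, 10, 3) array plus labels.  Raises naming the
    missing residue if a reference C-alpha cannot be found.
    """
    if structure.segment is None:
        raise ReconstructError("structure carries no dimer segmentation")
    segments = np.unique(structure.segment)
    labels = [("alpha",) + r for r in spec.alpha_refs] + [
        ("beta",) + r for r in spec.beta_refs
    ]
    out = np.zeros((len(segments), 10, 3))
    is_ca = structure.names == "CA"
    for si, seg in enumerate(segments):
        in_seg = structure.segment == seg
        # monomer with smaller mean z is the alpha subunit
        seg_chains = np.unique(structure.chains[in_seg])
        if len(seg_chains) != 2:
            raise ReconstructError(
                f"dimer segment {seg} must contain exactly two chains"
            )
        mean_z = [
            structure.coords[in_seg & (structure.chains == c), 2].mean()
            for c in seg_chains
        ]
        chain_of = {
            "alpha": seg_chains[int(np.argmin(mean_z))],
            "beta": seg_chains[int(np.argmax(mean_z))],
        }
        for pi, (mono, res_name, res_id) in enumerate(labels):
            sel = (
                in_seg
                & (structure.chains == chain_of[mono])
                & (structure.res_names == res_name)
                & (structure.res_ids == res_id)
                & is_ca
            )
            hits = np.flatnonzero(sel)
            if len(hits) != 1:
                raise ReconstructError(
                    f"reference residue {res_name}{res_id} ({mono}) "
                    f"missing or ambiguous in dimer segment {seg}"
                )
            out[si, pi] = structure.coords[hits[0]]
    return out, labels


def _cyl_objective(points, axis_xy, targets, theta):
    """Sum of squared radial deviations after rotating the rigid point set
    by theta about the vertical axis through ``axis_xy``."""
    c, s = np.cos(theta), np.sin(theta)
    rel = points[:, :2] - axis_xy
    x = c * rel[:, 0] - s * rel[:, 1] + axis_xy[0]
    y = s * rel[:, 0] + c * rel[:, 1] + axis_xy[1]
    rho = np.hypot(x, y)
    return float(np.sum((rho - targets) ** 2))


def reorient_about_axis(
    points: np.ndarray,
    dimer_axis_xy: np.ndarray,
    targets: np.ndarray,
    n_grid: int = 360,
) -> float:
    """Optimal rigid rotation angle (radians) of a reference point set
    about its dimer's vertical axis.

    Minimizes sum_i (rho_i(theta) - target_i)^2, where rho_i is the
    distance of point i from the global cylinder (z) axis, over a coarse
    angular grid refined by bounded scalar minimization.
    """
    points = np.asarray(points, dtype=float)
    axis_xy = np.asarray(dimer_axis_xy, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if np.all(np.hypot(*(points[:, :2] - axis_xy).T) < 1e-9):
        raise ReconstructError("all points lie on the dimer axis")
    thetas = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    vals = [_cyl_objective(points, axis_xy, targets, t) for t in thetas]
    best = int(np.argmin(vals))
    span = 2.0 * np.pi / n_grid
    lo, hi = thetas[best] - span, thetas[best] + span
    res = minimize_scalar(
        lambda t: _cyl_objective(points, axis_xy, targets, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(res.x)
    # wrap into (-pi, pi]
    return float(theta - 2.0 * np.pi * np.floor((theta + np.pi) / (2 * np.pi)))


def reference_radii_13_3(
    templates: dict, spec: ReorientSpec, lattice_spec=None
) -> np.ndarray:
    """Radial distances R_i of the 10 reference C-alpha atoms from the
    cylinder axis in the (azimuthally oriented) 13-3 lattice placement.

    By helical symmetry every dimer gives the same radii; a single dimer
    at azimuth zero is probed.
    """
    from .lattice import LatticeSpec, build_mt_lattice

    if lattice_spec is None:
        lattice_spec = LatticeSpec(n_dimers=1)
    else:
        from dataclasses import replace as _replace

        lattice_spec = _replace(lattice_spec, n_dimers=1)
    model = build_mt_lattice(lattice_spec)
    placed = place_on_beads(templates, model, orient_azimuthal=True)
    pts, _ = extract_reference_points(placed, spec)
    return np.hypot(pts[0, :, 0], pts[0, :, 1])


def build_atomic_hf(
    templates: dict,
    cg_model: BeadModel,
    spec: ReorientSpec,
) -> AtomicStructure:
    """Build the atomic filament: per dimer, place templates on beads,
    extract reference points, solve the two-stage cylindrical reorientation
    about the dimer axis, and superpose the full dimer onto the reoriented
    reference points.

    The reorientation objective is weighted by the stage force constant; a
    uniform weight does not move the optimum, so the second (stiff) stage
    acts as a refinement of the first.  Each dimer is transformed rigidly:
    internal geometry is exact.
    """
    radii = spec.reference_radii
    if radii is None:
        radii = reference_radii_13_3(templates, spec, cg_model.spec)
    targets = np.asarray(radii, dtype=float) + spec.r_cyldiff

    placed = place_on_beads(templates, cg_model, orient_azimuthal=False)
    pts_all, _ = extract_reference_points(placed, spec)
    com = cg_model.dimer_com()

    parts = []
    n_dimers = cg_model.n_dimers
    for d in range(n_dimers):
        axis_xy = com[d, :2]
        pts = pts_all[d]
        # two-stage schedule: coarse grid at the soft k, tight refinement
        # at the stiff k (same optimum; the grid resolution differs)
        theta = reorient_about_axis(pts, axis_xy, targets, n_grid=72)
        theta = _refine_theta(pts, axis_xy, targets, theta)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pivot = np.array([axis_xy[0], axis_xy[1], 0.0])
        reoriented = (pts - pivot) @ rot.T + pivot

        dimer = placed.select(placed.segment == d)
        tf, _ = kabsch_superpose(pts, reoriented)
        parts.append(dimer.with_coords(tf.apply(dimer.coords)))
    return AtomicStructure.concat(parts)


def _refine_theta(pts, axis_xy, targets, theta0, width=0.1):
    res = minimize_scalar(
        lambda t: _cyl_objective(pts, axis_xy, targets, t),
        bounds=(theta0 - width, theta0 + width),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)
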