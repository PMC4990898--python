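"""Kabsch superposition, reference-point extraction, cylindrical
reorientation, and the atomic filament round trip."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from helifil.lattice import ALPHA, BETA, LatticeSpec, build_mt_lattice
from helifil.reconstruct import (
    ReconstructError,
    ReorientSpec,
    RigidTransform,
    _cyl_objective,
    build_atomic_hf,
    extract_reference_points,
    kabsch_superpose,
    place_on_beads,
    reference_radii_13_3,
    reorient_about_axis,
)
from helifil.synth import ToyTemplateSpec, make_toy_monomer


def grid_rmsd_oracle(mobile, target, n=24):
    """Dense rotation-grid oracle for the minimal RMSD (Euler grid)."""
    mobile = mobile - mobile.mean(axis=0)
    target = target - target.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    half = np.linspace(0, np.pi, n // 2)
    for a in angles:
        for b in half:
            for c in angles:
                rot = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                rmsd = np.sqrt(
                    np.mean(np.sum((mobile @ rot.T - target) ** 2, axis=1))
                )
                best = min(best, rmsd)
    return best


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        mirror = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ReconstructError):
            RigidTransform(mirror, np.zeros(3))

    def test_apply(self):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        tf = RigidTransform(rot, np.array([1.0, 0, 0]))
        out = tf.apply(np.array([[1.0, 0, 0]]))
        np.testing.assert_allclose(out, [[1.0, 1.0, 0]], atol=1e-12)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        tf, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)

    def test_recovers_constructed_transform(self):
        tetra = np.array(
            [[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        )
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        target = tetra @ rot.T + np.array([3.0, -2.0, 5.0])
        tf, rmsd = kabsch_superpose(tetra, target)
        assert rmsd < 1e-8
        np.testing.assert_allclose(tf.apply(tetra), target, atol=1e-8)

    def test_mirror_image_stays_proper(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        tf, rmsd = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
        assert rmsd > 0.1
        oracle = grid_rmsd_oracle(pts, mirrored)
        # optimal against every grid rotation, and the grid closes in on it
        assert rmsd <= oracle + 1e-9
        assert oracle - rmsd < 0.05

    def test_count_mismatch_rejected(self):
        with pytest.raises(ReconstructError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_rejected(self):
        line = np.column_stack(
            (np.arange(5.0), np.zeros(5), np.zeros(5))
        )
        with pytest.raises(ReconstructError):
            kabsch_superpose(line, line + 1.0)

    def test_three_point_planar_closed_form(self):
        """For congruent planar triangles the optimal RMSD is zero and is
        found exactly."""
        tri = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4.0, 0]])
        rot = Rotation.from_euler("x", 75, degrees=True).as_matrix()
        tf, rmsd = kabsch_superpose(tri, tri @ rot.T + 2.0)
        assert rmsd == pytest.approx(0.0, abs=1e-10)


class TestPlacement:
    def test_com_on_every_bead(self, templates, small_spec,
                               small_lattice):
        placed = place_on_beads(templates, small_lattice)
        for b in range(len(small_lattice)):
            chain = placed.chains[b * 50]  # 50 atoms per toy monomer
            mono = placed.select(placed.chains == chain)
            np.testing.assert_allclose(
                mono.com(), small_lattice.positions[b], atol=1e-6
            )

    def test_internal_distances_preserved(self, templates):
        model = build_mt_lattice(LatticeSpec(n_dimers=1))
        placed = place_on_beads(templates, model)
        alpha = placed.select(placed.chains == "A")
        temp = templates[ALPHA]
        d_placed = np.linalg.norm(
            alpha.coords[:, None] - alpha.coords[None, :], axis=-1
        )
        d_temp = np.linalg.norm(
            temp.coords[:, None] - temp.coords[None, :], axis=-1
        )
        np.testing.assert_allclose(d_placed, d_temp, atol=1e-9)

    def test_missing_template_kind_rejected(self, templates,
                                            small_lattice):
        with pytest.raises(ReconstructError):
            place_on_beads({ALPHA: templates[ALPHA]}, small_lattice)


class TestReferencePoints:
    def test_ten_points_per_dimer(self, templates):
        model = build_mt_lattice(LatticeSpec(n_dimers=2))
        placed = place_on_beads(templates, model)
        pts, labels = extract_reference_points(placed, ReorientSpec())
        assert pts.shape == (2, 10, 3)
        assert len(labels) == 10

    def test_stable_ordering(self, templates):
        model = build_mt_lattice(LatticeSpec(n_dimers=1))
        placed = place_on_beads(templates, model)
        spec = ReorientSpec()
        a, _ = extract_reference_points(placed, spec)
        b, _ = extract_reference_points(placed, spec)
        np.testing.assert_array_equal(a, b)

    def test_missing_residue_named_in_error(self, templates, toy_spec):
        model = build_mt_lattice(LatticeSpec(n_dimers=1))
        broken_alpha = make_toy_monomer(toy_spec, ALPHA)
        hit = (broken_alpha.res_ids == 304) & (
            broken_alpha.res_names == "LYS"
        )
        broken_alpha.res_names[hit] = "GLY"
        placed = place_on_beads(
            {ALPHA: broken_alpha, BETA: templates[BETA]}, model
        )
        with pytest.raises(ReconstructError, match="LYS304"):
            extract_reference_points(placed, ReorientSpec())


class TestReorientation:
    def _satisfied_points(self, templates):
        """Reference points of an azimuthally oriented dimer, with the
        radii they already satisfy as targets."""
        model = build_mt_lattice(LatticeSpec(n_dimers=1))
        placed = place_on_beads(templates, model, orient_azimuthal=True)
        pts, _ = extract_reference_points(placed, ReorientSpec())
        pts = pts[0]
        targets = np.hypot(pts[:, 0], pts[:, 1])
        axis_xy = model.dimer_com()[0, :2]
        return pts, axis_xy, targets

    def test_zero_when_already_at_targets(self, templates):
        pts, axis_xy, targets = self._satisfied_points(templates)
        theta = reorient_about_axis(pts, axis_xy, targets)
        assert abs(theta) < 1e-6

    def test_recovers_inverse_of_applied_rotation(self, templates):
        pts, axis_xy, targets = self._satisfied_points(templates)
        psi = 0.7
        c, s = np.cos(psi), np.sin(psi)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        pivot = np.array([axis_xy[0], axis_xy[1], 0.0])
        rotated = (pts - pivot) @ rot.T + pivot
        theta = reorient_about_axis(rotated, axis_xy, targets)
        assert theta == pytest.approx(-psi, abs=1e-6)

    def test_optimum_beats_dense_grid(self, templates):
        rng = np.random.default_rng(8)
        pts, axis_xy, targets = self._satisfied_points(templates)
        for _ in range(3):
            jittered = targets + rng.normal(scale=3.0, size=10)
            theta = reorient_about_axis(pts, axis_xy, np.abs(jittered))
            best = _cyl_objective(pts, axis_xy, np.abs(jittered), theta)
            grid = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
            vals = [
                _cyl_objective(pts, axis_xy, np.abs(jittered), t)
                for t in grid
            ]
            assert best <= min(vals) + 1e-9
            assert abs(theta - grid[int(np.argmin(vals))]) < 2 * np.pi / 3600 + 1e-3

    def test_degenerate_axis_points_rejected(self):
        pts = np.zeros((10, 3))
        pts[:, 2] = np.arange(10.0)
        with pytest.raises(ReconstructError):
            reorient_about_axis(pts, np.zeros(2), np.ones(10))


class TestAtomicFilament:
    def test_13_3_round_trip_rmsd(self, templates):
        """Reconstructing from the 13-3 bead model with zero radial offset
        reproduces the azimuthally oriented atomic 13-3 placement."""
        spec13 = LatticeSpec(n_dimers=26)
        cg = build_mt_lattice(spec13)
        reference = place_on_beads(templates, cg, orient_azimuthal=True)
        recon = build_atomic_hf(templates, cg, ReorientSpec(r_cyldiff=0.0))
        for d in range(cg.n_dimers):
            a = reference.select(reference.segment == d).coords
            b = recon.select(recon.segment == d).coords
            rmsd = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert rmsd < 0.5

    def test_atom_count_and_rigidity(self, templates, hf_full):
        model, _ = hf_full
        sub = model.copy()
        keep = model.dimer_index < 4  # four dimers keep the test light
        sub.positions = model.positions[keep]
        sub.kinds = model.kinds[keep]
        sub.dimer_index = model.dimer_index[keep]
        sub.strand_index = model.strand_index[keep]
        sub.masses = model.masses[keep]
        recon = build_atomic_hf(
            templates, sub, ReorientSpec(r_cyldiff=77.0)
        )
        assert len(recon) == 4 * 2 * 50
        # rigidity: every placed monomer superposes exactly onto its
        # template (internal geometry untouched by the reconstruction)
        for chain in np.unique(recon.chains):
            mono = recon.select(recon.chains == chain)
            kind = ALPHA if mono.coords[:, 2].mean() < recon.select(
                recon.segment == mono.segment[0]
            ).coords[:, 2].mean() else BETA
            _, rmsd = kabsch_superpose(templates[kind].coords, mono.coords)
            assert rmsd < 1e-6

    def test_radial_ordering_preserved(self, templates, hf_full):
        """Reference residues keep their luminal-vs-outer radial order
        between the 13-3 lattice and the filament reconstruction."""
        model, _ = hf_full
        sub = model.copy()
        keep = model.dimer_index < 3
        sub.positions = model.positions[keep]
        sub.kinds = model.kinds[keep]
        sub.dimer_index = model.dimer_index[keep]
        sub.strand_index = model.strand_index[keep]
        sub.masses = model.masses[keep]
        spec = ReorientSpec(r_cyldiff=77.0)
        recon = build_atomic_hf(templates, sub, spec)
        pts, _ = extract_reference_points(recon, spec)
        radii_13_3 = reference_radii_13_3(templates, spec)
        for d in range(3):
            radii_hf = np.hypot(pts[d, :, 0], pts[d, :, 1])
            rho = spearmanr(radii_hf, radii_13_3).statistic
            assert rho == pytest.approx(1.0, abs=1e-9)

    def test_two_stage_objective_monotone(self, templates):
        """The stiff-stage refinement never worsens the cylindrical
        objective found by the soft stage."""
        from helifil.reconstruct import _refine_theta

        model = build_mt_lattice(LatticeSpec(n_dimers=5))
        placed = place_on_beads(templates, model)
        pts_all, _ = extract_reference_points(placed, ReorientSpec())
        targets = reference_radii_13_3(templates, ReorientSpec())
        com = model.dimer_com()
        for d in range(5):
            pts = pts_all[d]
            axis_xy = com[d, :2]
            theta1 = reorient_about_axis(pts, axis_xy, targets, n_grid=72)
            obj1 = _cyl_objective(pts, axis_xy, targets, theta1)
            theta2 = _refine_theta(pts, axis_xy, targets, theta1)
            obj2 = _cyl_objective(pts, axis_xy, targets, theta2)
            assert obj2 <= obj1 + 1e-12
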