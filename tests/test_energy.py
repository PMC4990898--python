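"""Coulomb, generalized-Born solvation, SASA, the subtraction scheme,
restrained sampling and ensemble pooling."""

import numpy as np
import pytest

from helifil.energy import (
    COULOMB_CONSTANT,
    EnergyError,
    ESModel,
    SamplerSpec,
    born_radii,
    coulomb_energy,
    gb_solvation_energy,
    interaction_energy,
    interaction_energy_ensemble,
    nonpolar_energy,
    pool_statistics,
    sample_restrained_snapshots,
    shrake_rupley_sasa,
    snapshot_plan,
)
from helifil.restraints import KB
from helifil.structure import AtomicStructure
from helifil.synth import ToyTemplateSpec, make_toy_dimer, make_toy_tetramer


def ion(q=1.0, radius=2.0, at=(0.0, 0.0, 0.0), rid=1):
    return AtomicStructure(
        names=["CA"], res_names=["GLY"], res_ids=[rid], chains=["A"],
        elements=["C"], coords=[at], charges=[q], radii=[radius],
    )


def two_atoms(q1, q2, r, radius=2.0):
    return AtomicStructure(
        names=["CA", "CA"], res_names=["GLY", "GLY"], res_ids=[1, 2],
        chains=["A", "B"], elements=["C", "C"],
        coords=[[0, 0, 0], [r, 0.0, 0.0]], charges=[q1, q2],
        radii=[radius, radius],
    )


class TestCoulomb:
    def test_constant_definition(self):
        """Opposite unit charges at r = 332.0636 A interact at exactly
        -1 kcal/mol."""
        st = two_atoms(1.0, -1.0, COULOMB_CONSTANT)
        assert coulomb_energy(st) == pytest.approx(-1.0, rel=1e-12)

    def test_single_atom_zero(self):
        assert coulomb_energy(ion()) == 0.0

    def test_three_atoms_equal_pairwise_sum(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=5, size=(3, 3))
        q = rng.normal(size=3)
        st = AtomicStructure(
            names=["CA"] * 3, res_names=["GLY"] * 3, res_ids=[1, 2, 3],
            chains=["A"] * 3, elements=["C"] * 3, coords=coords,
            charges=q, radii=np.ones(3),
        )
        oracle = sum(
            COULOMB_CONSTANT * q[i] * q[j]
            / np.linalg.norm(coords[i] - coords[j])
            for i in range(3)
            for j in range(i + 1, 3)
        )
        assert coulomb_energy(st) == pytest.approx(oracle, rel=1e-12)

    def test_missing_charges_rejected(self):
        st = ion()
        st.charges = None
        with pytest.raises(EnergyError):
            coulomb_energy(st)

    def test_coincident_charges_rejected(self):
        st = two_atoms(1.0, 1.0, 0.0)
        with pytest.raises(EnergyError):
            coulomb_energy(st)


class TestGeneralizedBorn:
    def test_born_ion_closed_form(self):
        """Single ion q = 1e, B = 2 A: the Born equation gives
        -0.5 (1 - 1/80) * 332.0636 / 2 = -81.98 kcal/mol."""
        expected = -0.5 * (1 - 1 / 80) * COULOMB_CONSTANT / 2.0
        assert gb_solvation_energy(ion()) == pytest.approx(
            expected, rel=1e-6
        )
        assert expected == pytest.approx(-81.98, abs=0.005)

    def test_zero_charges_zero_energy(self):
        st = two_atoms(0.0, 0.0, 10.0)
        assert gb_solvation_energy(st) == 0.0

    def test_distant_ions_reach_screened_closed_form(self):
        """At 500 A separation the energy is two Born self terms plus the
        screened cross term -(1 - 1/80) k q1 q2 / r."""
        r = 500.0
        st = two_atoms(1.0, 1.0, r)
        self_term = -0.5 * (1 - 1 / 80) * COULOMB_CONSTANT / 2.0
        cross = -(1 - 1 / 80) * COULOMB_CONSTANT / r
        assert gb_solvation_energy(st) == pytest.approx(
            2 * self_term + cross, abs=1e-3
        )

    def test_isolated_born_radius_is_intrinsic(self):
        st = ion(radius=1.7)
        assert born_radii(st)[0] == pytest.approx(1.7, rel=1e-12)

    def test_descreening_grows_born_radius(self):
        st = two_atoms(1.0, 1.0, 4.0)
        b = born_radii(st)
        assert np.all(b > 2.0)

    def test_missing_radii_rejected(self):
        st = ion()
        st.radii = None
        with pytest.raises(EnergyError):
            gb_solvation_energy(st)


class TestNonpolar:
    def test_isolated_sphere_closed_form(self):
        """SASA of one sphere is 4 pi (rho + probe)^2; at gamma = 0.03 a
        2 A atom contributes 4.358 kcal/mol."""
        st = ion(radius=2.0)
        sasa = shrake_rupley_sasa(st)[0]
        assert sasa == pytest.approx(4 * np.pi * 3.4**2, rel=1e-9)
        assert nonpolar_energy(st) == pytest.approx(4.358, abs=1e-3)

    def test_buried_atom_contributes_nothing(self):
        st = AtomicStructure(
            names=["CA", "CA"], res_names=["GLY"] * 2, res_ids=[1, 2],
            chains=["A"] * 2, elements=["C"] * 2,
            coords=[[0, 0, 0], [0.0, 0, 0.5]], charges=[0.0, 0.0],
            radii=[0.8, 8.0],
        )
        assert shrake_rupley_sasa(st)[0] == 0.0

    def test_distant_spheres_additive(self):
        st = two_atoms(0.0, 0.0, 1000.0, radius=2.0)
        together = nonpolar_energy(st)
        alone = nonpolar_energy(ion(q=0.0, radius=2.0))
        assert together == pytest.approx(2 * alone, rel=1e-9)


class TestInteraction:
    def test_cross_pair_coulomb_oracle(self):
        """For two one-atom 'dimers' the Coulomb interaction term equals
        the explicit cross-pair sum exactly."""
        st = two_atoms(0.7, -0.4, 12.0)
        rep = interaction_energy(st, ["A"], ["B"], include_nonpolar=False)
        oracle = COULOMB_CONSTANT * 0.7 * -0.4 / 12.0
        assert rep.e_coul_int == pytest.approx(oracle, rel=1e-10)

    def test_decomposition_identity_exact(self):
        tet = make_toy_tetramer("lateral13", ToyTemplateSpec(seed=2))
        rep = interaction_energy(tet, ["A", "B"], ["C", "D"],
                                 include_nonpolar=False)
        assert rep.e_total_int == rep.e_coul_int + rep.e_solv_int

    def test_separability_at_large_distance(self):
        """Neutral toy dimers 200+ A apart interact below 0.05 kcal/mol."""
        spec = ToyTemplateSpec(seed=4, charge_scheme="zero_sum")
        d1 = make_toy_dimer(spec, chains=("A", "B"))
        d2 = make_toy_dimer(spec, chains=("C", "D")).translated(
            (260.0, 0.0, 0.0)
        )
        tet = AtomicStructure.concat([d1, d2])
        rep = interaction_energy(tet, ["A", "B"], ["C", "D"],
                                 include_nonpolar=False)
        assert abs(rep.e_total_int) < 0.05

    def test_sign_structure_like_charged_dimers(self):
        """Net-negative dimers at a contact interface: the Coulomb term is
        repulsive and solvent screening opposes it."""
        tet = make_toy_tetramer("lateral13", ToyTemplateSpec(seed=2))
        rep = interaction_energy(tet, ["A", "B"], ["C", "D"],
                                 include_nonpolar=False)
        assert rep.e_coul_int > 0
        assert rep.e_solv_int < 0

    def test_overlapping_selections_rejected(self):
        tet = make_toy_tetramer("lateral13", ToyTemplateSpec(seed=2))
        with pytest.raises(EnergyError):
            interaction_energy(tet, ["A", "B"], ["B", "C"])

    def test_selections_must_cover(self):
        tet = make_toy_tetramer("lateral13", ToyTemplateSpec(seed=2))
        with pytest.raises(EnergyError):
            interaction_energy(tet, ["A"], ["C", "D"])


class TestSampler:
    def test_snapshot_count_and_determinism(self):
        base = make_toy_dimer(ToyTemplateSpec(seed=6, n_atoms=15))
        spec = SamplerSpec(n_snapshots=7, stride=5, equilibration=10,
                           seed=21)
        runs = [sample_restrained_snapshots(base, spec) for _ in range(2)]
        assert len(runs[0]) == 7
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_empty_selection_rejected(self):
        base = make_toy_dimer(ToyTemplateSpec(seed=6, n_atoms=15))
        base.backbone[:] = False
        with pytest.raises(EnergyError):
            sample_restrained_snapshots(base, SamplerSpec(n_snapshots=2))

    def test_positional_variance_matches_boltzmann(self):
        """k = 1 kcal/mol/A^2 tethers at 300 K: per-dimension displacement
        variance approaches kB*T/(2k) = 0.298 A^2."""
        base = make_toy_dimer(ToyTemplateSpec(seed=3, n_atoms=12))
        spec = SamplerSpec(
            k=1.0, temperature=300.0, n_snapshots=400, stride=100,
            equilibration=1000, seed=5, k_repulsion=0.0,
        )
        snaps = sample_restrained_snapshots(base, spec)
        disp = np.array([s.coords - base.coords for s in snaps])
        var = disp.reshape(len(snaps), -1).var(axis=0).mean()
        assert var == pytest.approx(KB * 300.0 / 2.0, rel=0.10)


class TestSnapshotPlan:
    def test_published_defaults(self):
        plan = snapshot_plan()
        assert plan.per_replica == 990
        assert plan.per_system == 4950
        assert plan.total_simulations == 20

    def test_no_equilibration(self):
        assert snapshot_plan(equil_ps=0.0).per_replica == 1000

    def test_single_replica(self):
        assert snapshot_plan(replicas=1).per_system == 990

    def test_non_divisible_stride_rejected(self):
        with pytest.raises(EnergyError):
            snapshot_plan(save_ps=7.0)

    def test_equilibration_must_fit(self):
        with pytest.raises(EnergyError):
            snapshot_plan(sim_length_ps=10.0, equil_ps=10.0)


class TestPooling:
    def test_hand_computed_example(self):
        summary = pool_statistics([[1.0, 3.0], [5.0, 7.0]])
        assert summary.replica_means == (2.0, 6.0)
        assert summary.pooled_mean == pytest.approx(4.0)
        assert summary.pooled_sd == pytest.approx(2.581988897, rel=1e-9)

    def test_constant_values_zero_sd(self):
        summary = pool_statistics([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert summary.replica_sds == (0.0, 0.0)
        assert summary.pooled_sd == 0.0

    def test_equal_n_pooled_mean_identity(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=50) for _ in range(5)]
        summary = pool_statistics(groups)
        assert summary.pooled_mean == pytest.approx(
            np.mean(summary.replica_means), abs=1e-10
        )

    def test_empty_replica_rejected(self):
        with pytest.raises(EnergyError):
            pool_statistics([[1.0], []])

    def test_ensemble_table_shape(self):
        base = make_toy_tetramer("longitudinal", ToyTemplateSpec(seed=9))
        snaps = sample_restrained_snapshots(
            base, SamplerSpec(n_snapshots=3, stride=5, equilibration=5,
                              seed=2)
        )
        table = interaction_energy_ensemble(
            snaps, ["A", "B"], ["C", "D"], include_nonpolar=False,
            replica=1,
        )
        assert len(table) == 3
        np.testing.assert_allclose(
            table["e_total_int"],
            table["e_coul_int"] + table["e_solv_int"],
        )
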