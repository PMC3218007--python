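"""Pairwise MM energies, SASA, binding series and per-residue decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ecdkit.binding_energy import (
    COULOMB_CONSTANT,
    EnergyModel,
    binding_energy_series,
    decompose_per_residue,
    delta_sasa,
    interaction_energy,
    sasa,
)
from ecdkit.synthetic_data import (
    ToyComplexSpec,
    assign_toy_parameters,
    build_toy_complex,
)
from ecdkit.trajectory_io import AtomSelection, Topology, Trajectory

import oracles


def _toy_system(n_atoms, charges, sigmas=None, epsilons=None, seed=0,
                spread=6.0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-spread, spread, size=(n_atoms, 3))
    top = Topology(
        atom_name=[f"X{i}" for i in range(n_atoms)],
        element=["C"] * n_atoms,
        res_id=np.arange(1, n_atoms + 1),
        res_name=["LIG"] * n_atoms,
        chain_id=["A"] * (n_atoms // 2) + ["B"] * (n_atoms - n_atoms // 2),
        charge=np.asarray(charges, dtype=float),
        lj_sigma=np.asarray(sigmas if sigmas is not None
                            else np.full(n_atoms, 3.2), dtype=float),
        lj_epsilon=np.asarray(epsilons if epsilons is not None
                              else np.full(n_atoms, 0.1), dtype=float),
    )
    return coords, top


class TestInteractionEnergy:
    def test_unit_charges_at_coulomb_distance(self):
        """Two +1e charges at r = k gives exactly 1 kcal/mol."""
        coords = np.array([[0.0, 0, 0], [COULOMB_CONSTANT, 0, 0]])
        top = Topology(atom_name=["A1", "B1"], element=["C", "C"],
                       res_id=[1, 2], res_name=["L", "L"],
                       chain_id=["A", "B"],
                       charge=np.array([1.0, 1.0]),
                       lj_sigma=np.zeros(2), lj_epsilon=np.zeros(2))
        model = EnergyModel()
        ele, vdw = interaction_energy(
            coords, top, model,
            AtomSelection(np.array([0]), 2), AtomSelection(np.array([1]), 2))
        assert ele == pytest.approx(1.0, abs=1e-12)
        assert vdw == 0.0

    def test_zero_charges_zero_electrostatics(self):
        coords, top = _toy_system(6, np.zeros(6))
        ele, _ = interaction_energy(
            coords, top, EnergyModel(),
            AtomSelection(np.arange(3), 6), AtomSelection(np.arange(3, 6), 6))
        assert ele == 0.0

    def test_ten_atom_toy_matches_double_loop_oracle(self):
        coords, top = _toy_system(
            10, np.linspace(-0.8, 0.8, 10),
            sigmas=np.linspace(2.5, 3.8, 10),
            epsilons=np.linspace(0.05, 0.3, 10), seed=4)
        ga, gb = np.arange(5), np.arange(5, 10)
        model = EnergyModel()
        ele, vdw = interaction_energy(
            coords, top, model,
            AtomSelection(ga, 10), AtomSelection(gb, 10))
        o_ele, o_vdw = oracles.pairwise_energy_loops(
            coords, top.charge, top.lj_sigma, top.lj_epsilon, ga, gb)
        assert ele == pytest.approx(o_ele, abs=1e-10)
        assert vdw == pytest.approx(o_vdw, abs=1e-10)

    def test_clash_and_missing_parameters(self):
        coords, top = _toy_system(4, np.ones(4))
        coords[2] = coords[0] + 0.01
        with pytest.raises(ValueError, match="clash"):
            interaction_energy(coords, top, EnergyModel(),
                               AtomSelection(np.arange(2), 4),
                               AtomSelection(np.arange(2, 4), 4))
        top.charge[1] = np.nan
        with pytest.raises(ValueError, match="missing energy parameters"):
            interaction_energy(coords, top, EnergyModel(),
                               AtomSelection(np.arange(2), 4),
                               AtomSelection(np.arange(2, 4), 4))

    def test_translation_rotation_invariance(self):
        coords, top = _toy_system(8, np.linspace(-0.5, 0.5, 8), seed=2)
        ga = AtomSelection(np.arange(4), 8)
        gb = AtomSelection(np.arange(4, 8), 8)
        model = EnergyModel()
        e1 = interaction_energy(coords, top, model, ga, gb)
        rot = Rotation.from_euler("xyz", [0.4, 1.2, -0.8])
        moved = rot.apply(coords) + np.array([10.0, -4.0, 2.0])
        e2 = interaction_energy(moved, top, model, ga, gb)
        assert e1[0] == pytest.approx(e2[0], rel=1e-12)
        assert e1[1] == pytest.approx(e2[1], rel=1e-12)


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        """Single carbon: 4*pi*(r+probe)^2 within 1% quadrature error."""
        top = Topology(atom_name=["C1"], element=["C"], res_id=[1],
                       res_name=["LIG"], chain_id=["A"])
        area = sasa(np.zeros((1, 3)), top)
        expected = oracles.sphere_sasa(1.70)
        assert area.sum() == pytest.approx(expected, rel=0.01)

    def test_fully_overlapping_atoms(self):
        """Two coincident atoms expose exactly one atom's surface."""
        top = Topology(atom_name=["C1", "C2"], element=["C", "C"],
                       res_id=[1, 1], res_name=["LIG", "LIG"],
                       chain_id=["A", "A"])
        area = sasa(np.zeros((2, 3)), top)
        assert area.sum() == pytest.approx(oracles.sphere_sasa(1.70),
                                           rel=0.01)

    def test_dumbbell_matches_analytic_two_sphere(self):
        top = Topology(atom_name=["C1", "O1"], element=["C", "O"],
                       res_id=[1, 2], res_name=["L", "L"],
                       chain_id=["A", "A"])
        d = 2.2
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        area = sasa(coords, top)
        expected = oracles.two_sphere_sasa(1.70, 1.52, d)
        assert area.sum() == pytest.approx(expected, rel=0.01)

    def test_quadrature_converges_monotonically(self):
        """Single-sphere quadrature error shrinks monotonically in the
        point count."""
        top = Topology(atom_name=["C1"], element=["C"], res_id=[1],
                       res_name=["LIG"], chain_id=["A"])
        exact = oracles.sphere_sasa(1.70)
        errors = []
        for points in (60, 240, 960, 3840):
            model = EnergyModel(sasa_points=points)
            errors.append(abs(sasa(np.zeros((1, 3)), top, model).sum()
                              - exact))
        assert all(b <= a for a, b in zip(errors, errors[1:]))


class TestBindingSeries:
    @pytest.fixture(scope="class")
    def charged_complex(self):
        spec = ToyComplexSpec(
            n_protein_residues=3, n_dna_basepairs=2,
            direct_hbonds=[(("A", 101, "OG"), ("C", 301, "OP1"))], seed=1)
        traj, top, _ = build_toy_complex(spec)
        top = assign_toy_parameters(top)
        traj = Trajectory(traj.coordinates, top)
        receptor = top.select(chain_id="A")
        ligand = top.select(chain_id=["C", "D"])
        return traj, top, receptor, ligand

    def test_attractive_complex_negative_energy(self, charged_complex):
        """Opposite charges in contact: the binding estimate is negative."""
        traj, top, receptor, ligand = charged_complex
        out = binding_energy_series(traj, EnergyModel(), receptor, ligand)
        assert out["mean"] < 0

    def test_separation_limit(self, charged_complex):
        """With charges off, moving the ligand 500 A away leaves only a
        vanishing LJ tail and zero buried surface: |dBE| < 1e-6."""
        traj, top, receptor, ligand = charged_complex
        coords = traj.coordinates.copy()
        coords[:, ligand.indices, :] += np.array([500.0, 0, 0])
        neutral = Topology(
            atom_name=top.atom_name, element=top.element,
            res_id=top.res_id, res_name=top.res_name,
            chain_id=top.chain_id, charge=np.zeros(top.n_atoms),
            lj_sigma=top.lj_sigma, lj_epsilon=top.lj_epsilon)
        far = Trajectory(coords, neutral)
        out = binding_energy_series(far, EnergyModel(), receptor, ligand)
        assert abs(out["mean"]) < 1e-6

    def test_charged_separation_tail_is_small(self, charged_complex):
        """With the toy charges on (neutral protein, -1e nucleotides) the
        500 A tail is a sub-0.05 kcal/mol multipole remnant."""
        traj, top, receptor, ligand = charged_complex
        coords = traj.coordinates.copy()
        coords[:, ligand.indices, :] += np.array([500.0, 0, 0])
        far = Trajectory(coords, top)
        out = binding_energy_series(far, EnergyModel(), receptor, ligand)
        assert abs(out["mean"]) < 0.05

    def test_single_frame_hand_summed(self):
        """Two atoms, one per group: series total = k q1 q2 / r + LJ +
        gamma * dSASA, each term summed by hand."""
        r = 4.0
        coords = np.array([[[0.0, 0, 0], [r, 0, 0]]])
        top = Topology(atom_name=["C1", "C2"], element=["C", "C"],
                       res_id=[1, 2], res_name=["L", "L"],
                       chain_id=["A", "B"],
                       charge=np.array([0.5, -0.5]),
                       lj_sigma=np.array([3.2, 3.2]),
                       lj_epsilon=np.array([0.1, 0.1]))
        traj = Trajectory(coords, top)
        model = EnergyModel()
        ga = AtomSelection(np.array([0]), 2)
        gb = AtomSelection(np.array([1]), 2)
        out = binding_energy_series(traj, model, ga, gb)
        e_ele = COULOMB_CONSTANT * 0.5 * -0.5 / r
        sr6 = (3.2 / r) ** 6
        e_vdw = 4 * 0.1 * (sr6 ** 2 - sr6)
        dA, _ = delta_sasa(coords[0], top, model, ga, gb)
        assert out["mean"] == pytest.approx(
            e_ele + e_vdw + model.gamma * dA, abs=1e-10)
        assert dA < 0  # surface is buried on contact

    def test_external_polar_and_entropy_terms(self, charged_complex):
        traj, top, receptor, ligand = charged_complex
        base = binding_energy_series(traj, EnergyModel(), receptor, ligand)
        polar = np.full(traj.n_frames, 2.5)
        out = binding_energy_series(traj, EnergyModel(), receptor, ligand,
                                    external_polar=polar,
                                    external_entropy=4.0)
        assert out["mean"] == pytest.approx(base["mean"] + 2.5 + 4.0,
                                            abs=1e-9)
        assert out["includes_polar"] and out["includes_entropy"]

    def test_overlapping_selections_rejected(self, charged_complex):
        traj, top, receptor, _ = charged_complex
        with pytest.raises(ValueError, match="overlap"):
            binding_energy_series(traj, EnergyModel(), receptor, receptor)


class TestDecomposition:
    @pytest.fixture(scope="class")
    def decomposition(self):
        spec = ToyComplexSpec(
            n_protein_residues=3, n_dna_basepairs=2,
            direct_hbonds=[(("A", 101, "OG"), ("C", 301, "OP1"))], seed=1)
        traj, top, _ = build_toy_complex(spec)
        top = assign_toy_parameters(top)
        traj = Trajectory(traj.coordinates, top)
        receptor = top.select(chain_id="A")
        ligand = top.select(chain_id=["C", "D"])
        model = EnergyModel()
        decomp = decompose_per_residue(traj, model, receptor, ligand)
        return traj, model, receptor, ligand, decomp

    def test_conservation_each_side_sums_to_total(self, decomposition):
        """Residue contributions are an exact partition (1e-6 relative):
        each side's pairwise terms sum to the totals, and the two sides'
        surface shares sum to the total buried-area term."""
        traj, model, receptor, ligand, decomp = decomposition
        ele, vdw = interaction_energy(
            traj.coordinates[0], traj.topology, model, receptor, ligand)
        dA, _ = delta_sasa(traj.coordinates[0], traj.topology, model,
                           receptor, ligand)
        for side in ("receptor", "ligand"):
            assert decomp.side_sum(side, "E_ele") == pytest.approx(
                ele, rel=1e-6)
            assert decomp.side_sum(side, "E_vdw") == pytest.approx(
                vdw, rel=1e-6)
        assert decomp.table["E_nonpolar"].sum() == pytest.approx(
            model.gamma * dA, rel=1e-6)
        assert decomp.total_ele == pytest.approx(ele, rel=1e-9)
        assert decomp.total_vdw == pytest.approx(vdw, rel=1e-9)

    def test_neutral_lj_free_residue_contributes_nothing(self):
        coords, top = _toy_system(6, [0.5, -0.5, 0.0, 0.4, -0.4, 0.3],
                                  seed=7, spread=4.0)
        top.charge[2] = 0.0
        top.lj_epsilon[2] = 0.0
        traj = Trajectory(coords[np.newaxis], top)
        decomp = decompose_per_residue(
            traj, EnergyModel(), AtomSelection(np.arange(3), 6),
            AtomSelection(np.arange(3, 6), 6), include_sasa=False)
        row = decomp.table[(decomp.table["side"] == "receptor")
                           & (decomp.table["res_id"] == 3)]
        assert abs(float(row["total"].iloc[0])) < 1e-12

    def test_two_residue_toy_matches_brute_force(self):
        coords, top = _toy_system(4, [0.3, -0.2, 0.25, -0.35], seed=9,
                                  spread=4.0)
        traj = Trajectory(coords[np.newaxis], top)
        ga, gb = np.arange(2), np.arange(2, 4)
        decomp = decompose_per_residue(
            traj, EnergyModel(), AtomSelection(ga, 4),
            AtomSelection(gb, 4), include_sasa=False)
        for res in (1, 2):
            o_ele, o_vdw = oracles.pairwise_energy_loops(
                coords, top.charge, top.lj_sigma, top.lj_epsilon,
                [res - 1], gb)
            row = decomp.table[(decomp.table["side"] == "receptor")
                               & (decomp.table["res_id"] == res)]
            assert float(row["E_ele"].iloc[0]) == pytest.approx(
                o_ele, abs=1e-10)
            assert float(row["E_vdw"].iloc[0]) == pytest.approx(
                o_vdw, abs=1e-10)

    def test_relative_to_reference_and_threshold(self, decomposition):
        *_, decomp = decomposition
        rel = decomp.relative_to(decomp)
        assert np.allclose(rel["total"], 0.0, atol=1e-12)
        sig = decomp.significant(threshold=1.0)
        assert (sig["total"].abs() >= 1.0).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_property(self, seed):
        """Decomposition conservation holds for random charges/geometry."""
        rng = np.random.default_rng(seed)
        coords, top = _toy_system(8, rng.uniform(-1, 1, 8), seed=seed,
                                  spread=5.0)
        traj = Trajectory(coords[np.newaxis], top)
        ga = AtomSelection(np.arange(4), 8)
        gb = AtomSelection(np.arange(4, 8), 8)
        model = EnergyModel()
        decomp = decompose_per_residue(traj, model, ga, gb,
                                       include_sasa=False)
        ele, vdw = interaction_energy(coords, top, model, ga, gb)
        assert decomp.side_sum("receptor") == pytest.approx(
            ele + vdw, rel=1e-9, abs=1e-9)
        assert decomp.side_sum("ligand") == pytest.approx(
            ele + vdw, rel=1e-9, abs=1e-9)
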