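"""Segment PCA, truncation rule, flexibility and correlation descriptor."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ecdkit.essential_dynamics import (
    compute_subspace,
    correlation_descriptor,
    flexibility_profile,
    residue_correlation,
    split_segments,
)
from ecdkit.synthetic_data import (
    PlantedModeSpec,
    chain_topology,
    generate_planted_trajectory,
    random_orthonormal_modes,
)
from ecdkit.trajectory_io import AtomSelection, Trajectory

import oracles


def _full_selection(traj):
    return AtomSelection(np.arange(traj.n_atoms), traj.n_atoms)


class TestSplitSegments:
    def test_five_segments_of_2000_frames(self):
        """1 ns sampled at 0.1 ps split into 0.2 ns segments -> 5 x 2000."""
        traj = Trajectory(np.zeros((10_000, 2, 3)), chain_topology(2),
                          frame_times=0.1 * np.arange(10_000))
        segments = split_segments(traj, 200.0)
        assert len(segments) == 5
        assert all(s.n_frames == 2000 for s in segments)

    def test_exact_single_segment(self):
        traj = Trajectory(np.zeros((100, 2, 3)), chain_topology(2),
                          frame_times=1.0 * np.arange(100))
        assert len(split_segments(traj, 100.0)) == 1

    def test_remainder_dropped(self, caplog):
        traj = Trajectory(np.zeros((500, 2, 3)), chain_topology(2),
                          frame_times=1.0 * np.arange(500))
        with caplog.at_level("WARNING"):
            segments = split_segments(traj, 200.0)
        assert len(segments) == 2
        assert any("dropping" in rec.message for rec in caplog.records)

    def test_segment_longer_than_trajectory(self):
        traj = Trajectory(np.zeros((10, 2, 3)), chain_topology(2),
                          frame_times=1.0 * np.arange(10))
        with pytest.raises(ValueError, match="longer than trajectory"):
            split_segments(traj, 100.0)


class TestComputeSubspace:
    def test_planted_mode_recovered(self, single_mode_trajectory):
        """Single planted mode, amplitude 4 A^2, no noise: leading
        eigenvalue ~4 and eigenvector overlap > 0.99."""
        traj, modes = single_mode_trajectory
        sub, coords = compute_subspace(traj, _full_selection(traj))
        assert sub.eigenvalues[0] == pytest.approx(4.0, rel=0.05)
        assert abs(sub.eigenvectors[:, 0] @ modes[0]) > 0.99

    def test_static_trajectory_zero_eigenvalues(self):
        traj = Trajectory(np.ones((10, 4, 3)), chain_topology(4))
        sub, _ = compute_subspace(traj, _full_selection(traj))
        assert np.all(sub.eigenvalues == 0.0)

    def test_trace_conservation(self, single_mode_trajectory):
        """Sum of eigenvalues equals the total mean-square displacement
        summed over coordinates (direct-sum oracle)."""
        traj, _ = single_mode_trajectory
        seg = traj.slice_frames(0, 500)
        sub, _ = compute_subspace(seg, _full_selection(seg))
        flat = seg.coordinates.reshape(seg.n_frames, -1)
        mean = flat.mean(axis=0)
        total_msd = sum(
            np.mean((flat[:, a] - mean[a]) ** 2)
            for a in range(flat.shape[1])
        )
        assert sub.eigenvalues.sum() == pytest.approx(total_msd,
                                                      rel=1e-6)

    def test_truncation_rule(self, single_mode_trajectory):
        """K = max(k_min, count reaching min_fraction), capped at 3N."""
        traj, _ = single_mode_trajectory
        sub, _ = compute_subspace(traj, _full_selection(traj))
        assert sub.K == 20  # 3N = 30, noise-free: one mode has 100%
        sub2, _ = compute_subspace(traj, _full_selection(traj), k_min=2)
        assert sub2.K == 2 and sub2.fraction_displacement > 0.99

    def test_orthonormality_and_nonnegativity(self, single_mode_trajectory):
        traj, _ = single_mode_trajectory
        sub, _ = compute_subspace(traj.slice_frames(0, 200),
                                  _full_selection(traj))
        gram = sub.eigenvectors.T @ sub.eigenvectors
        assert np.max(np.abs(gram - np.eye(sub.K))) < 1e-8
        assert np.all(sub.eigenvalues >= 0)

    def test_unsuperposed_input_warns(self):
        coords = np.zeros((20, 3, 3))
        coords[:, :, 0] += np.arange(20)[:, None] * 0.5  # drifting
        traj = Trajectory(coords + np.random.default_rng(0).normal(
            scale=0.01, size=coords.shape), chain_topology(3))
        with pytest.warns(UserWarning, match="drift"):
            compute_subspace(traj, _full_selection(traj))


class TestFlexibility:
    def test_identical_atoms_equal_flexibility(self):
        """Atoms with duplicated coordinates have identical F (symmetry)."""
        rng = np.random.default_rng(5)
        one_atom = rng.normal(size=(50, 1, 3))
        coords = np.repeat(one_atom, 4, axis=1)
        traj = Trajectory(coords, chain_topology(4))
        sel = _full_selection(traj)
        _, ecoords = compute_subspace(traj, sel)
        profile = flexibility_profile([ecoords], sel, traj)
        assert np.allclose(profile["F_mean"], profile["F_mean"].iloc[0],
                           atol=1e-6)

    def test_planted_mobile_atom_is_maximum(self):
        """The atom carrying a large-amplitude planted mode tops F."""
        n = 8
        mode = np.zeros(3 * n)
        mode[3 * 2] = 1.0  # atom 2, x direction
        spec = PlantedModeSpec(
            n_atoms=n, n_frames=2000, mode_vectors=mode[np.newaxis],
            mode_amplitudes=np.array([9.0]), noise_sigma=0.3, seed=13)
        traj = generate_planted_trajectory(spec, np.zeros((n, 3)))
        sel = _full_selection(traj)
        _, ecoords = compute_subspace(traj, sel)
        profile = flexibility_profile([ecoords], sel, traj)
        assert profile["F_mean"].idxmax() == 2

    def test_matches_one_shot_oracle(self, single_mode_trajectory):
        """Full pipeline F and d equal a direct one-shot script to 1e-8."""
        traj, _ = single_mode_trajectory
        seg = traj.slice_frames(0, 300)
        sel = _full_selection(seg)
        sub, ecoords = compute_subspace(seg, sel)
        profile = flexibility_profile([ecoords], sel, seg)
        vals, vecs, k, flex_oracle, d_oracle = oracles.essential_descriptors(
            seg.coordinates, k_min=20, min_fraction=0.8)
        assert sub.K == k
        np.testing.assert_allclose(profile["F_mean"], flex_oracle,
                                   atol=1e-8)
        d_ours = correlation_descriptor(ecoords, sel, sel)
        np.testing.assert_allclose(d_ours, d_oracle, atol=1e-8)

    def test_empty_calpha_rejected(self, single_mode_trajectory):
        traj, _ = single_mode_trajectory
        _, ecoords = compute_subspace(traj.slice_frames(0, 50),
                                      _full_selection(traj))
        with pytest.raises(ValueError, match="empty"):
            flexibility_profile([ecoords],
                                AtomSelection(np.array([], dtype=int),
                                              traj.n_atoms))


class TestCorrelationDescriptor:
    def test_self_distance_zero_and_metric(self, single_mode_trajectory):
        traj, _ = single_mode_trajectory
        seg = traj.slice_frames(0, 400)
        sel = _full_selection(seg)
        _, ecoords = compute_subspace(seg, sel)
        d = correlation_descriptor(ecoords, sel, sel)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-10

    def test_antiphase_closed_form(self):
        """Two atoms in exact anti-phase along one mode: d equals twice the
        sqrt-eigenvalue-scaled per-atom component, 2*sqrt(l1)*|E_i|."""
        n = 2
        mode = np.zeros(3 * n)
        mode[0] = 1 / np.sqrt(2)   # atom 0 +x
        mode[3] = -1 / np.sqrt(2)  # atom 1 -x (anti-phase)
        spec = PlantedModeSpec(
            n_atoms=n, n_frames=4000, mode_vectors=mode[np.newaxis],
            mode_amplitudes=np.array([4.0]), noise_sigma=0.0, seed=3)
        traj = generate_planted_trajectory(
            spec, np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        sel = _full_selection(traj)
        sub, ecoords = compute_subspace(traj, sel)
        d = correlation_descriptor(
            ecoords,
            AtomSelection(np.array([0]), n), AtomSelection(np.array([1]), n))
        lam = sub.eigenvalues[0]
        expected = 2.0 * np.sqrt(lam) * abs(sub.eigenvectors[0, 0])
        assert d[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_bound_pair_more_correlated_than_free(self):
        """Atoms sharing a planted mode sit closer in essential space than
        atoms driven by independent modes, in >= 95% of replicates."""
        n = 6
        shared = np.zeros(3 * n)
        shared[0] = shared[3] = 1 / np.sqrt(2)   # atoms 0,1 together
        solo_a = np.zeros(3 * n)
        solo_a[6] = 1.0                          # atom 2 alone
        solo_b = np.zeros(3 * n)
        solo_b[9] = 1.0                          # atom 3 alone
        modes = np.stack([shared, solo_a, solo_b])
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            spec = PlantedModeSpec(
                n_atoms=n, n_frames=500, mode_vectors=modes,
                mode_amplitudes=np.array([4.0, 3.9, 3.8]),
                noise_sigma=0.5, seed=seed)
            traj = generate_planted_trajectory(spec, np.zeros((n, 3)))
            sel = _full_selection(traj)
            _, ecoords = compute_subspace(traj, sel)
            d = correlation_descriptor(ecoords, sel, sel)
            if d[0, 1] < d[2, 3]:
                wins += 1
        assert wins / n_rep >= 0.95

    def test_rigid_transform_invariance(self, single_mode_trajectory):
        """d is unchanged when all frames are rigidly moved (the fit and
        the covariance both remove global motion)."""
        traj, _ = single_mode_trajectory
        seg = traj.slice_frames(0, 300)
        sel = _full_selection(seg)
        _, e1 = compute_subspace(seg, sel)
        d1 = correlation_descriptor(e1, sel, sel)
        rot = Rotation.from_euler("xyz", [0.7, -0.2, 1.9])
        moved = np.array([rot.apply(f) + np.array([3.0, -8.0, 2.0])
                          for f in seg.coordinates])
        seg2 = Trajectory(moved, seg.topology)
        _, e2 = compute_subspace(seg2, sel)
        d2 = correlation_descriptor(e2, sel, sel)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_residue_reduction_minimum(self, toy_complex):
        """Residue-level d is the minimum over the residue's atoms."""
        traj, top, _ = toy_complex
        from ecdkit.synthetic_data import simulate_complex_trajectory
        from ecdkit.synthetic_data import ToyComplexSpec

        spec = ToyComplexSpec(n_protein_residues=2, n_dna_basepairs=2,
                              seed=4)
        moving, _ = simulate_complex_trajectory(spec, n_frames=300)
        sel = AtomSelection(np.arange(moving.n_atoms), moving.n_atoms)
        _, ecoords = compute_subspace(moving, sel)
        probe = int(moving.topology.select(
            chain_id="A", res_id=101, atom_name="OG").indices[0])
        dna = moving.topology.select(chain_id="C")
        table = residue_correlation([ecoords], probe, dna, moving)
        d_all = correlation_descriptor(
            ecoords, AtomSelection(np.array([probe]), moving.n_atoms), dna)
        res_ids = moving.topology.res_id[dna.indices]
        for _, row in table.iterrows():
            mask = res_ids == row["res_id"]
            assert row["d_mean"] == pytest.approx(
                d_all[0][mask].min(), rel=1e-12)
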