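import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ecdkit.synthetic_data import (
    ConformationMixtureSpec,
    PlantedModeSpec,
    ToyComplexSpec,
    build_toy_complex,
    generate_conformation_mixture,
    generate_planted_trajectory,
    random_orthonormal_modes,
)


@pytest.fixture(scope="session")
def reference_coords():
    """A 10-atom zig-zag chain used as the planted-mode reference."""
    rng = np.random.default_rng(42)
    base = np.cumsum(rng.normal(scale=1.5, size=(10, 3)), axis=0)
    return base - base.mean(axis=0)


@pytest.fixture(scope="session")
def single_mode_trajectory(reference_coords):
    """Noise-free trajectory with one planted mode of amplitude 4 A^2."""
    n_atoms = len(reference_coords)
    modes = random_orthonormal_modes(n_atoms, 1, seed=7)
    spec = PlantedModeSpec(
        n_atoms=n_atoms, n_frames=10_000, mode_vectors=modes,
        mode_amplitudes=np.array([4.0]), noise_sigma=0.0, seed=11,
    )
    return generate_planted_trajectory(spec, reference_coords), modes


@pytest.fixture(scope="session")
def two_state_mixture():
    """500-frame 50/50 mixture of two well-separated conformations."""
    rng = np.random.default_rng(3)
    conf_a = rng.normal(scale=3.0, size=(12, 3))
    conf_b = conf_a + rng.normal(scale=6.0, size=(12, 3))
    spec = ConformationMixtureSpec(
        reference_conformations=[conf_a, conf_b],
        weights=np.array([0.5, 0.5]),
        noise_sigma=1.0, n_frames=500, seed=5,
    )
    traj, labels = generate_conformation_mixture(spec)
    return traj, labels, (conf_a, conf_b)


@pytest.fixture(scope="session")
def toy_complex():
    """Toy complex with 3 direct bonds and 2 water bridges planted."""
    spec = ToyComplexSpec(
        n_protein_residues=6, n_dna_basepairs=4,
        direct_hbonds=[(("A", 101, "OG"), ("C", 301, "OP1")),
                       (("A", 102, "N"), ("C", 302, "O6")),
                       (("A", 103, "OG"), ("D", 351, "N3"))],
        bridge_waters=[(104, 303), (105, ("D", 352, "O2"))],
        seed=0,
    )
    return build_toy_complex(spec)
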