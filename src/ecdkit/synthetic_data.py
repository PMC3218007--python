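"""Synthetic trajectories, conformation mixtures and toy complexes.

Every analysis stage in this package is exercised against data with known
ground truth: Gaussian fluctuations around a reference dominated by a few
planted collective modes (what the covariance analysis assumes), mixtures
of discrete conformations plus noise (what clustering assumes), and small
protein/DNA/water complexes in which exactly a requested set of hydrogen
bonds and single-water bridges is geometrically realized.

All generators take an explicit seed; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectory_io import Topology, Trajectory

__all__ = [
    "PlantedModeSpec",
    "ConformationMixtureSpec",
    "ToyComplexSpec",
    "AtomRef",
    "chain_topology",
    "random_orthonormal_modes",
    "generate_planted_trajectory",
    "generate_conformation_mixture",
    "build_toy_complex",
]

#: (chain_id, res_id, atom_name) triple identifying one atom.
AtomRef = tuple[str, int, str]

# Plausible (not force-field accurate) point charges for toy complexes, by
# atom name; protein residues net 0 e, nucleotides net -1 e, waters net 0.
_TOY_CHARGES: dict[str, float] = {
    "N": -0.40, "H": 0.40, "CA": 0.00, "C": 0.50, "O": -0.50,
    "OG": -0.40, "HG": 0.40,
    "P": 1.50, "OP1": -0.78, "OP2": -0.78, "O5'": -0.40, "C1'": 0.20,
    "N9": 0.05, "N7": -0.25, "O6": -0.35, "N3": -0.28, "N2": 0.09,
    "N1": 0.05, "O2": -0.35, "N4": -0.16,
}
_TOY_WATER_CHARGES = {"O": -0.834, "H1": 0.417, "H2": 0.417}

# Lennard-Jones parameters by element (sigma A, epsilon kcal/mol).
_TOY_LJ: dict[str, tuple[float, float]] = {
    "H": (1.07, 0.0157), "C": (3.40, 0.0860), "N": (3.25, 0.1700),
    "O": (2.96, 0.2100), "P": (3.74, 0.2000), "S": (3.56, 0.2500),
}


def assign_toy_parameters(topology: Topology) -> Topology:
    """Return a copy of the topology with toy charges and LJ parameters."""
    charge = np.zeros(topology.n_atoms)
    sigma = np.zeros(topology.n_atoms)
    epsilon = np.zeros(topology.n_atoms)
    water = topology.is_water()
    for i in range(topology.n_atoms):
        name = topology.atom_name[i]
        if water[i]:
            charge[i] = _TOY_WATER_CHARGES.get(name, 0.0)
        else:
            charge[i] = _TOY_CHARGES.get(name, 0.0)
        sigma[i], epsilon[i] = _TOY_LJ.get(topology.element[i], (3.0, 0.1))
    return Topology(
        atom_name=topology.atom_name.copy(),
        element=topology.element.copy(),
        res_id=topology.res_id.copy(),
        res_name=topology.res_name.copy(),
        chain_id=topology.chain_id.copy(),
        charge=charge, lj_sigma=sigma, lj_epsilon=epsilon,
    )


def chain_topology(n_atoms: int, chain_id: str = "A") -> Topology:
    """A minimal Calpha-trace topology: one GLY CA pseudo-atom per residue."""
    return Topology(
        atom_name=np.array(["CA"] * n_atoms),
        element=np.array(["C"] * n_atoms),
        res_id=np.arange(1, n_atoms + 1),
        res_name=np.array(["GLY"] * n_atoms),
        chain_id=np.array([chain_id] * n_atoms),
    )


def random_orthonormal_modes(n_atoms: int, n_modes: int,
                             seed: int) -> np.ndarray:
    """``(n_modes, 3*n_atoms)`` mutually orthonormal random directions."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((3 * n_atoms, n_modes))
    q, _ = np.linalg.qr(raw)
    return q.T[:n_modes]


# --------------------------------------------------------------------------
# Planted collective modes
# --------------------------------------------------------------------------

@dataclass
class PlantedModeSpec:
    """Trajectory = reference + sum_k sqrt(amp_k) a_k(t) M_k + noise.

    ``mode_amplitudes`` are target covariance eigenvalues in A^2 (sorted
    descending); ``noise_sigma`` is the isotropic per-coordinate standard
    deviation in A.  Time coefficients a_k(t) are i.i.d. standard normal
    per frame (no autocorrelation): the covariance analysis only sees
    second moments, not dynamics.
    """

    n_atoms: int
    n_frames: int
    mode_vectors: np.ndarray  # (n_modes, 3*n_atoms)
    mode_amplitudes: np.ndarray  # (n_modes,) A^2
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode_vectors = np.atleast_2d(
            np.asarray(self.mode_vectors, dtype=np.float64))
        self.mode_amplitudes = np.atleast_1d(
            np.asarray(self.mode_amplitudes, dtype=np.float64))
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        n_modes, dim = self.mode_vectors.shape
        if dim != 3 * self.n_atoms:
            raise ValueError(
                f"mode vectors have dimension {dim}, expected {3*self.n_atoms}"
            )
        if len(self.mode_amplitudes) != n_modes:
            raise ValueError("one amplitude per mode required")
        if np.any(self.mode_amplitudes < 0):
            raise ValueError("mode amplitudes must be non-negative")
        if np.any(np.diff(self.mode_amplitudes) > 0):
            raise ValueError("mode amplitudes must be sorted descending")
        gram = self.mode_vectors @ self.mode_vectors.T
        if not np.allclose(gram, np.eye(n_modes), atol=1e-8):
            raise ValueError("mode vectors must be mutually orthonormal")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def generate_planted_trajectory(
    spec: PlantedModeSpec,
    reference: np.ndarray,
    dt_ps: float = 0.1,
    topology: Topology | None = None,
) -> Trajectory:
    """Sample a trajectory whose covariance is sum_k amp_k M_k M_k^T + s^2 I.

    Deterministic under a fixed ``spec.seed``.  Frame times are spaced
    ``dt_ps`` picoseconds apart (0.1 ps default, a typical MD save rate).
    """
    ref = np.asarray(reference, dtype=np.float64).reshape(-1)
    if ref.shape[0] != 3 * spec.n_atoms:
        raise ValueError(
            f"reference has {ref.shape[0]} coordinates, "
            f"expected {3 * spec.n_atoms}"
        )
    rng = np.random.default_rng(spec.seed)
    n_modes = spec.mode_vectors.shape[0]
    coeffs = rng.standard_normal((spec.n_frames, n_modes))
    flat = ref[np.newaxis, :] + (
        coeffs * np.sqrt(spec.mode_amplitudes)[np.newaxis, :]
    ) @ spec.mode_vectors
    if spec.noise_sigma > 0:
        flat = flat + spec.noise_sigma * rng.standard_normal(flat.shape)
    coords = flat.reshape(spec.n_frames, spec.n_atoms, 3)
    top = topology if topology is not None else chain_topology(spec.n_atoms)
    times = dt_ps * np.arange(spec.n_frames)
    return Trajectory(coords, top, frame_times=times)


# --------------------------------------------------------------------------
# Conformation mixtures
# --------------------------------------------------------------------------

@dataclass
class ConformationMixtureSpec:
    """Frames drawn from discrete conformations with isotropic jitter."""

    reference_conformations: Sequence[np.ndarray]
    weights: np.ndarray
    noise_sigma: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        confs = [np.asarray(c, dtype=np.float64) for c in
                 self.reference_conformations]
        if not confs:
            raise ValueError("at least one conformation required")
        shape = confs[0].shape
        if shape[-1] != 3 or confs[0].ndim != 2:
            raise ValueError("conformations must be (n_atoms, 3) arrays")
        for c in confs:
            if c.shape != shape:
                raise ValueError("all conformations must share atom count")
        self.reference_conformations = confs
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(confs),):
            raise ValueError("one weight per conformation required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"weights sum to {self.weights.sum():.12f}, expected 1"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        # separation precondition: clusters must be resolvable
        if len(confs) >= 2 and self.noise_sigma > 0:
            for i in range(len(confs)):
                for j in range(i + 1, len(confs)):
                    d = np.sqrt(np.mean(
                        np.sum((confs[i] - confs[j]) ** 2, axis=1)))
                    if d < 5.0 * self.noise_sigma:
                        raise ValueError(
                            f"conformations {i} and {j} are {d:.3f} A apart "
                            f"(RMSD), below 5*noise_sigma = "
                            f"{5 * self.noise_sigma:.3f} A"
                        )


def generate_conformation_mixture(
    spec: ConformationMixtureSpec,
    dt_ps: float = 2.0,
    topology: Topology | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Return (trajectory, per-frame true conformation labels)."""
    rng = np.random.default_rng(spec.seed)
    n_conf = len(spec.reference_conformations)
    labels = rng.choice(n_conf, size=spec.n_frames, p=spec.weights)
    base = np.stack(spec.reference_conformations)[labels]
    if spec.noise_sigma > 0:
        base = base + spec.noise_sigma * rng.standard_normal(base.shape)
    n_atoms = base.shape[1]
    top = topology if topology is not None else chain_topology(n_atoms)
    times = dt_ps * np.arange(spec.n_frames)
    return Trajectory(base, top, frame_times=times), labels


# --------------------------------------------------------------------------
# Toy protein-DNA-water complexes
# --------------------------------------------------------------------------

# Serine-like protein residue template (local coordinates, Angstrom).
# Donors: backbone N (H) and hydroxyl OG (HG); acceptors: O, OG, N.
_PROTEIN_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.95, -0.35, 0.00)),
    ("CA", "C", (1.40, 0.45, 0.00)),
    ("C", "C", (2.55, -0.45, 0.25)),
    ("O", "O", (2.75, -1.60, 0.30)),
    ("OG", "O", (1.55, 1.85, 0.55)),
    ("HG", "H", (1.50, 2.82, 0.45)),
]

# Hydrogen attached to each donor atom in the protein template.
_PROTEIN_DONOR_H = {"N": "H", "OG": "HG"}

# Guanine / cytosine nucleotides, hydrogens omitted: the toy DNA is an
# acceptor-only ladder, which keeps planted edge sets exact.
_DG_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("P", "P", (0.00, 0.00, 0.00)),
    ("OP1", "O", (1.25, 0.70, 0.00)),
    ("OP2", "O", (-1.25, 0.70, 0.00)),
    ("O5'", "O", (0.00, -1.45, 0.00)),
    ("C1'", "C", (0.30, 1.20, 1.30)),
    ("N9", "N", (0.30, 2.50, 1.50)),
    ("N7", "N", (1.50, 4.50, 1.60)),
    ("O6", "O", (0.30, 6.20, 1.70)),
    ("N3", "N", (-1.40, 3.00, 1.50)),
    ("N2", "N", (-2.70, 4.60, 1.60)),
]

_DC_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("P", "P", (0.00, 0.00, 0.00)),
    ("OP1", "O", (-1.25, 0.70, 0.00)),
    ("OP2", "O", (1.25, 0.70, 0.00)),
    ("O5'", "O", (0.00, -1.45, 0.00)),
    ("C1'", "C", (-0.30, 1.20, 1.30)),
    ("N1", "N", (-0.30, 2.50, 1.50)),
    ("O2", "O", (0.90, 3.10, 1.50)),
    ("N3", "N", (0.20, 4.40, 1.60)),
    ("N4", "N", (-0.80, 6.00, 1.70)),
]

_RISE = 12.0          # A between stacked nucleotides (exaggerated ladder)
_STRAND_SEP = 16.0    # A between the two strands
_PROTEIN_X = -25.0    # resting x of unplaced protein residues
_PROTEIN_SPACING = 12.0
_DONOR_ACCEPTOR_DIST = 2.9   # A, planted D...A distance
_BRIDGE_SPAN = 5.6           # A, protein O ... DNA acceptor across a water
_WATER_LEG = 2.8             # A, water O to each bridge acceptor


@dataclass
class ToyComplexSpec:
    """Requested hydrogen-bond content of a single-frame toy complex.

    ``direct_hbonds`` are (donor AtomRef, acceptor AtomRef) pairs; the
    donor must belong to a protein residue (chain "A", serine-like
    template with donors N and OG).  ``bridge_waters`` are
    (protein_res_id, dna AtomRef-or-res_id) pairs joined through one
    water donating to the protein carbonyl O and to the DNA acceptor.
    """

    n_protein_residues: int
    n_dna_basepairs: int
    bridge_waters: Sequence[tuple[int, int | AtomRef]] = field(
        default_factory=list)
    direct_hbonds: Sequence[tuple[AtomRef, AtomRef]] = field(
        default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protein_residues < 1:
            raise ValueError("need at least one protein residue")
        if self.n_dna_basepairs < 1:
            raise ValueError("need at least one DNA base pair")


class _Builder:
    def __init__(self) -> None:
        self.names: list[str] = []
        self.elements: list[str] = []
        self.res_ids: list[int] = []
        self.res_names: list[str] = []
        self.chains: list[str] = []
        self.coords: list[np.ndarray] = []

    def add_residue(self, template, chain: str, res_id: int, res_name: str,
                    origin: np.ndarray) -> None:
        for name, el, xyz in template:
            self.names.append(name)
            self.elements.append(el)
            self.res_ids.append(res_id)
            self.res_names.append(res_name)
            self.chains.append(chain)
            self.coords.append(np.asarray(xyz) + origin)

    def atom_index(self, chain: str, res_id: int, name: str) -> int:
        for i, (c, r, n) in enumerate(
                zip(self.chains, self.res_ids, self.names)):
            if c == chain and r == res_id and n == name:
                return i
        raise KeyError(f"no atom {chain}:{res_id}:{name}")

    def residue_indices(self, chain: str, res_id: int) -> list[int]:
        return [i for i, (c, r) in enumerate(zip(self.chains, self.res_ids))
                if c == chain and r == res_id]

    def move_residue(self, chain: str, res_id: int,
                     new_coords: np.ndarray) -> None:
        idx = self.residue_indices(chain, res_id)
        for k, i in enumerate(idx):
            self.coords[i] = new_coords[k]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _orthonormal_frame(primary: np.ndarray,
                       secondary: np.ndarray) -> np.ndarray:
    """Right-handed frame with the first axis exactly along ``primary``."""
    p = _unit(primary)
    s = secondary - np.dot(secondary, p) * p
    if np.linalg.norm(s) < 1e-8:
        fallback = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(fallback, p)) > 0.9:
            fallback = np.array([1.0, 0.0, 0.0])
        s = fallback - np.dot(fallback, p) * p
    s = _unit(s)
    return np.column_stack([p, s, np.cross(p, s)])


def _rigid_from_axes(p_from: np.ndarray, s_from: np.ndarray,
                     p_to: np.ndarray, s_to: np.ndarray) -> np.ndarray:
    """Rotation mapping p_from exactly onto p_to, s_from toward s_to."""
    return _orthonormal_frame(p_to, s_to) @ _orthonormal_frame(
        p_from, s_from).T


def _fibonacci_directions(n: int = 64) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_CLEARANCE_DIST = 3.55       # detector cutoff 3.5 A plus margin
_CLEARANCE_DEVIATION = 55.0  # detector cutoff 50 deg plus margin
_H_CLEARANCE = 1.30          # > 1.25 A: no mis-assigned covalent hydrogen


def _placement_clear(new_coords: np.ndarray, new_elements: Sequence[str],
                     old_coords: np.ndarray, old_elements: np.ndarray,
                     allowed: set[tuple[int, int]]) -> bool:
    """True if placing the new atoms creates no unplanned cross-group bond.

    Applies the same donor/hydrogen/acceptor criterion as the detector
    (with a 0.05 A / 5 deg safety margin) to pairs spanning the new and
    existing atom groups.  ``allowed`` holds (new local index, existing
    local index) pairs that are deliberately close (the planted
    donor/acceptor geometry).  Proximity alone is not a clash: a pair is
    only rejected if one side is a donor whose hydrogen makes the contact
    nearly linear.
    """
    if len(old_coords) == 0:
        return True
    n_new = len(new_coords)
    coords = np.vstack([new_coords, old_coords])
    elements = list(new_elements) + list(old_elements)
    polar = [i for i, e in enumerate(elements) if e in ("N", "O")]
    if not polar:
        return True
    polar_coords = np.array([coords[i] for i in polar])
    donor_h: dict[int, list[int]] = {}
    for h, e in enumerate(elements):
        if e != "H":
            continue
        dists = np.linalg.norm(polar_coords - coords[h], axis=1)
        j = int(np.argmin(dists))
        if dists[j] <= _H_CLEARANCE:
            p = polar[j]
            if (h < n_new) != (p < n_new):
                return False  # hydrogen glued onto a foreign heavy atom
            donor_h.setdefault(p, []).append(h)

    def _near_linear(donor: int, acceptor: int) -> bool:
        for h in donor_h.get(donor, ()):
            v1 = coords[donor] - coords[h]
            v2 = coords[acceptor] - coords[h]
            cosang = np.dot(v1, v2) / (
                np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if 180.0 - ang < _CLEARANCE_DEVIATION:
                return True
        return False

    for p in polar:
        for q in polar:
            if (p < n_new) == (q < n_new):  # same group: not a cross pair
                continue
            i, j = (p, q - n_new) if p < n_new else (q, p - n_new)
            if (i, j) in allowed:
                continue
            if np.linalg.norm(coords[p] - coords[q]) > _CLEARANCE_DIST:
                continue
            if _near_linear(p, q) or _near_linear(q, p):
                return False
    return True


def build_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[Trajectory, Topology, set]:
    """Construct a single-frame complex realizing exactly the planted bonds.

    Returns (trajectory, topology, expected contact set) where the contact
    set uses the same canonical representation as
    :func:`ecdkit.hbond_network.contact_set`: ``("direct", {resA, resB})``
    for direct bonds and ``("water", {resA, resB}, water)`` for bridges,
    residues keyed as (chain_id, res_id).

    Raises ``ValueError`` naming the offending bond if the request is not
    realizable, and re-runs the geometric detector to guarantee that the
    emitted structure contains the planted edges and nothing else.
    """
    b = _Builder()
    # protein column
    for i in range(spec.n_protein_residues):
        b.add_residue(_PROTEIN_TEMPLATE, "A", 101 + i, "SER",
                      np.array([_PROTEIN_X, 0.0, i * _PROTEIN_SPACING]))
    # DNA ladder: strand C (DG, ascending z), strand D (DC)
    for i in range(spec.n_dna_basepairs):
        b.add_residue(_DG_TEMPLATE, "C", 301 + i, "DG",
                      np.array([0.0, 0.0, i * _RISE]))
        b.add_residue(_DC_TEMPLATE, "D", 351 + i, "DC",
                      np.array([_STRAND_SEP, 0.0, i * _RISE]))

    used_protein: set[int] = set()

    def _claim_protein(res_id: int, what: str) -> None:
        if res_id in used_protein:
            raise ValueError(
                f"protein residue {res_id} used by more than one planted "
                f"feature ({what}); not realizable"
            )
        if res_id < 101 or res_id >= 101 + spec.n_protein_residues:
            raise ValueError(f"protein residue {res_id} does not exist")
        used_protein.add(res_id)

    template_coords = np.array([xyz for _, _, xyz in _PROTEIN_TEMPLATE])
    template_names = [nm for nm, _, _ in _PROTEIN_TEMPLATE]
    template_elements = [el for _, el, _ in _PROTEIN_TEMPLATE]

    def _outward(chain: str, res_id: int, a_pos: np.ndarray) -> np.ndarray:
        idx = b.residue_indices(chain, res_id)
        centroid = np.mean([b.coords[i] for i in idx], axis=0)
        return _unit(a_pos - centroid)

    def _env(exclude_res: tuple[str, int]) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray]:
        """Existing coordinates/elements outside the moving residue."""
        keep = [i for i in range(len(b.coords))
                if (b.chains[i], b.res_ids[i]) != exclude_res]
        coords = np.array([b.coords[i] for i in keep]) if keep \
            else np.zeros((0, 3))
        els = np.array([b.elements[i] for i in keep])
        return coords, els, np.array(keep, dtype=int)

    def _try_place(exclude_res: tuple[str, int], make_atoms) -> bool:
        """Search approach directions/spins; commit the first clash-free."""
        old_coords, old_els, keep_idx = _env(exclude_res)
        pos_in_env = {g: k for k, g in enumerate(keep_idx)}
        for u in candidate_dirs:
            for spin in spin_vectors(u):
                placed = make_atoms(u, spin)
                if placed is None:
                    continue
                new_coords, new_els, allowed_pairs = placed
                allowed = {
                    (i, pos_in_env[g]) for i, g in allowed_pairs
                    if g in pos_in_env
                }
                if _placement_clear(new_coords, new_els, old_coords,
                                    old_els, allowed):
                    return True
        return False

    def spin_vectors(u: np.ndarray):
        base = _orthonormal_frame(u, np.array([0.0, 0.0, 1.0]))[:, 1]
        for ang in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            yield (np.cos(ang) * base
                   + np.sin(ang) * np.cross(u, base))

    expected: set = set()

    # ---- direct bonds ----
    for donor_ref, acceptor_ref in spec.direct_hbonds:
        dchain, dres, dname = donor_ref
        achain, ares, aname = acceptor_ref
        if dchain != "A":
            raise ValueError(
                f"direct bond {donor_ref}->{acceptor_ref}: only protein "
                f"(chain A) donors are supported in the toy builder"
            )
        if dname not in _PROTEIN_DONOR_H:
            raise ValueError(
                f"direct bond {donor_ref}->{acceptor_ref}: atom {dname} "
                f"is not a donor (no attached hydrogen)"
            )
        _claim_protein(dres, f"direct bond to {acceptor_ref}")
        try:
            a_global = b.atom_index(achain, ares, aname)
        except KeyError as exc:
            raise ValueError(
                f"direct bond {donor_ref}->{acceptor_ref}: {exc}"
            ) from exc
        a_pos = np.array(b.coords[a_global])
        outward = _outward(achain, ares, a_pos)
        dirs = _fibonacci_directions()
        candidate_dirs = dirs[np.argsort(-dirs @ outward)]
        d_local = template_coords[template_names.index(dname)]
        h_local = template_coords[template_names.index(
            _PROTEIN_DONOR_H[dname])]
        d_i = template_names.index(dname)
        h_i = template_names.index(_PROTEIN_DONOR_H[dname])
        body_local = template_coords.mean(axis=0) - d_local
        committed: dict = {}

        def make_direct(u, spin, *, d_local=d_local, h_local=h_local,
                        body_local=body_local, a_pos=a_pos,
                        d_i=d_i, h_i=h_i, a_global=a_global,
                        committed=committed):
            rot = _rigid_from_axes(h_local - d_local, body_local,
                                   -u, spin)
            new = (template_coords - d_local) @ rot.T \
                + a_pos + _DONOR_ACCEPTOR_DIST * u
            committed["coords"] = new
            # donor and its hydrogen are deliberately close to the acceptor
            return new, template_elements, {(d_i, a_global),
                                            (h_i, a_global)}

        if not _try_place(("A", dres), make_direct):
            raise ValueError(
                f"direct bond {donor_ref}->{acceptor_ref}: no clash-free "
                f"placement found; geometry not realizable"
            )
        b.move_residue("A", dres, committed["coords"])
        expected.add(("direct",
                      frozenset({("A", dres), (achain, ares)})))

    # ---- water bridges ----
    water_id = 1
    for prot_res, dna in spec.bridge_waters:
        if isinstance(dna, tuple):
            achain, ares, aname = dna
        else:
            achain, ares, aname = "C", int(dna), "OP1"
        _claim_protein(prot_res, f"bridge to {achain}:{ares}")
        try:
            a_global = b.atom_index(achain, ares, aname)
        except KeyError as exc:
            raise ValueError(f"bridge {prot_res}->{dna}: {exc}") from exc
        a_pos = np.array(b.coords[a_global])
        outward = _outward(achain, ares, a_pos)
        dirs = _fibonacci_directions()
        candidate_dirs = dirs[np.argsort(-dirs @ outward)]
        o_local = template_coords[template_names.index("O")]
        o_i = template_names.index("O")
        body_local = template_coords.mean(axis=0) - o_local
        committed = {}

        def make_bridge(u, spin, *, o_local=o_local, body_local=body_local,
                        a_pos=a_pos, o_i=o_i, a_global=a_global,
                        committed=committed):
            # protein residue anchored by its carbonyl O across the water,
            # body pointing away from the DNA acceptor
            rot = _rigid_from_axes(body_local, template_coords[0] - o_local,
                                   u, spin)
            res_coords = (template_coords - o_local) @ rot.T \
                + a_pos + _BRIDGE_SPAN * u
            o_wat = a_pos + _WATER_LEG * u
            new = np.vstack([res_coords,
                             o_wat, o_wat - 1.0 * u, o_wat + 1.0 * u])
            els = template_elements + ["O", "H", "H"]
            committed["res"] = res_coords
            committed["water"] = (o_wat, u)
            n = len(template_coords)
            # water O and its DNA-side H sit close to the acceptor by design
            return new, els, {(n, a_global), (n + 1, a_global)}

        if not _try_place(("A", prot_res), make_bridge):
            raise ValueError(
                f"bridge {prot_res}->{achain}:{ares}: no clash-free "
                f"placement found; geometry not realizable"
            )
        b.move_residue("A", prot_res, committed["res"])
        o_wat, u = committed["water"]
        wkey = 901 + (water_id - 1)
        b.add_residue([("O", "O", (0.0, 0.0, 0.0))], "W", wkey, "HOH", o_wat)
        # one H toward each acceptor, exactly linear
        b.add_residue([("H1", "H", (0.0, 0.0, 0.0))], "W", wkey, "HOH",
                      o_wat - 1.0 * u)
        b.add_residue([("H2", "H", (0.0, 0.0, 0.0))], "W", wkey, "HOH",
                      o_wat + 1.0 * u)
        expected.add(("water",
                      frozenset({("A", prot_res), (achain, ares)}),
                      ("W", wkey)))
        water_id += 1

    coords = np.stack(b.coords)[np.newaxis]
    top = Topology(
        atom_name=np.array(b.names),
        element=np.array(b.elements),
        res_id=np.array(b.res_ids),
        res_name=np.array(b.res_names),
        chain_id=np.array(b.chains),
    )
    traj = Trajectory(coords, top)

    # round-trip guarantee: the detector must see exactly the planted set
    from . import hbond_network as hb

    hbonds = hb.detect_hbonds(coords[0], top)
    bridges = hb.detect_water_bridges(top, hbonds)
    detected = hb.contact_set(top, hbonds, bridges)
    if detected != expected:
        spurious = detected - expected
        missing = expected - detected
        raise ValueError(
            "toy complex geometry not realizable as requested; "
            f"spurious edges: {sorted(map(str, spurious))}; "
            f"missing edges: {sorted(map(str, missing))}"
        )
    return traj, top, expected


def simulate_complex_trajectory(
    spec: ToyComplexSpec,
    n_frames: int = 200,
    noise_sigma: float = 0.05,
    n_modes: int = 3,
    mode_amplitude: float = 0.25,
    dt_ps: float = 5.0,
    seed: int | None = None,
) -> tuple[Trajectory, set]:
    """Animate a toy complex: planted low-dimensional modes plus jitter.

    The single-frame toy complex becomes an ``n_frames`` trajectory with
    a few random orthonormal collective modes (amplitudes decaying from
    ``mode_amplitude`` A^2) and isotropic noise -- small enough that the
    planted hydrogen-bond geometry survives in every frame.  The topology
    carries toy charges and LJ parameters so every pipeline stage can run.
    Returns the trajectory and the expected contact set.
    """
    frame0, top, expected = build_toy_complex(spec)
    top = assign_toy_parameters(top)
    the_seed = spec.seed if seed is None else seed
    n_atoms = top.n_atoms
    amplitudes = mode_amplitude * np.power(
        0.7, np.arange(max(1, n_modes)))
    modes = random_orthonormal_modes(n_atoms, len(amplitudes), the_seed)
    planted = PlantedModeSpec(
        n_atoms=n_atoms, n_frames=n_frames, mode_vectors=modes,
        mode_amplitudes=amplitudes, noise_sigma=noise_sigma,
        seed=the_seed,
    )
    return generate_planted_trajectory(
        planted, frame0.coordinates[0], dt_ps=dt_ps, topology=top
    ), expected
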