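"""Essential collective dynamics: segment PCA, flexibility and correlation.

The covariance matrix of mean-centered Cartesian displacements is built
over short trajectory segments (default 0.2 ns) and diagonalized.  The
top-K eigenvectors — at least 20 modes and at least 80% of the total
mean-square displacement — span the *essential subspace*.  Each atom i
owns a 3-vector slice of every retained eigenvector; stacking the K
slices (scaled by sqrt(eigenvalue) under the default weighting) gives the
atom's essential coordinates, a point in 3K-space.  Two descriptors are
derived from distances in that space:

* flexibility ``F_i``: distance of a Calpha atom's essential coordinates
  from the centroid over all Calpha atoms — large F marks mobile regions;
* correlation descriptor ``d(i, j)``: distance between two atoms'
  essential coordinates — small d means strongly coupled motion and is
  read as persistent interaction (e.g. between a side chain and DNA).

Both are averaged over segments, with the per-segment spread retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory_io import AtomSelection, Trajectory

__all__ = [
    "EssentialSubspace",
    "AtomEssentialCoordinates",
    "split_segments",
    "compute_subspace",
    "flexibility_profile",
    "correlation_descriptor",
    "residue_correlation",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_MIN_FRACTION = 0.8


@dataclass
class EssentialSubspace:
    """Eigen-decomposition of one segment's displacement covariance."""

    eigenvalues: np.ndarray      # all 3n values, descending, A^2
    eigenvectors: np.ndarray     # (3n, K) orthonormal columns
    K: int
    fraction_displacement: float
    atom_indices: np.ndarray     # selection rows -> global atom indices
    segment_id: int = 0

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("negative eigenvalue in essential subspace")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        gram = self.eigenvectors.T @ self.eigenvectors
        if np.max(np.abs(gram - np.eye(self.K))) > 1e-8:
            raise ValueError("eigenvectors are not orthonormal")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class AtomEssentialCoordinates:
    """Per-atom slices of the essential eigenvectors.

    ``eps[i, k]`` is atom i's 3-vector share of mode k, scaled by
    sqrt(eigenvalue_k) under the default weighting (so dominant modes
    dominate distances); ``flat`` concatenates the K slices into one
    3K-vector per atom.  The unscaled slices of each mode have unit total
    norm (the eigenvector normalization redistributed over atoms).
    """

    eps: np.ndarray              # (n_atoms, K, 3)
    atom_indices: np.ndarray
    weighting: str               # "sqrt_lambda" | "unweighted"
    segment_id: int = 0

    @property
    def flat(self) -> np.ndarray:
        n = self.eps.shape[0]
        return self.eps.reshape(n, -1)

    def rows_for(self, selection: AtomSelection | np.ndarray) -> np.ndarray:
        """Map global atom indices to rows of this coordinate table."""
        wanted = selection.indices if isinstance(selection, AtomSelection) \
            else np.asarray(selection)
        lookup = {int(g): r for r, g in enumerate(self.atom_indices)}
        try:
            return np.array([lookup[int(g)] for g in wanted], dtype=int)
        except KeyError as exc:
            raise ValueError(
                f"atom {exc} is not part of the essential subspace selection"
            ) from exc


def split_segments(traj: Trajectory,
                   segment_length_ps: float) -> list[Trajectory]:
    """Contiguous non-overlapping segments; a trailing remainder is dropped.

    Frame spacing is taken from ``frame_times`` (1 ps/frame is assumed,
    with a warning, when times are absent).
    """
    if traj.frame_times is not None and traj.n_frames > 1:
        dt = float(traj.frame_times[1] - traj.frame_times[0])
    else:
        warnings.warn("trajectory has no frame times; assuming 1 ps/frame")
        dt = 1.0
    frames_per_segment = int(round(segment_length_ps / dt))
    if frames_per_segment < 2:
        raise ValueError("segment shorter than two frames")
    if frames_per_segment > traj.n_frames:
        raise ValueError(
            f"segment of {segment_length_ps} ps ({frames_per_segment} "
            f"frames) longer than trajectory ({traj.n_frames} frames)"
        )
    n_segments = traj.n_frames // frames_per_segment
    remainder = traj.n_frames - n_segments * frames_per_segment
    if remainder:
        logger.warning(
            "dropping %d trailing frames not filling a %s ps segment",
            remainder, segment_length_ps,
        )
    return [
        traj.slice_frames(s * frames_per_segment,
                          (s + 1) * frames_per_segment)
        for s in range(n_segments)
    ]


def _rigid_drift(coords: np.ndarray) -> float:
    """Net systematic centroid drift over a segment (superposition check).

    A least-squares linear trend of the centroid against time separates
    genuine drift (unsuperposed input) from stationary fluctuation, which
    legitimately moves the centroid frame to frame.
    """
    centroids = coords.mean(axis=1)
    t = np.arange(len(centroids), dtype=np.float64)
    t -= t.mean()
    denom = (t ** 2).sum()
    if denom == 0:
        return 0.0
    slope = (t[:, None] * (centroids - centroids.mean(axis=0))).sum(0) / denom
    return float(np.linalg.norm(slope) * (len(centroids) - 1))


def compute_subspace(
    segment: Trajectory,
    selection: AtomSelection,
    k_min: int = DEFAULT_K,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    weighting: str = "sqrt_lambda",
    segment_id: int = 0,
    drift_tolerance: float = 1.0,
) -> tuple[EssentialSubspace, AtomEssentialCoordinates]:
    """Covariance PCA of one (superposed) segment on ``selection``.

    K is ``max(k_min, smallest count reaching min_fraction)`` capped at 3n,
    honoring both the fixed-20 and the >=80%-of-displacement truncation
    rules.  The per-atom essential coordinates are scaled by
    sqrt(eigenvalue) unless ``weighting="unweighted"``.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    if segment.n_frames < 2:
        raise ValueError("need at least two frames for a covariance")
    if weighting not in ("sqrt_lambda", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    coords = segment.coordinates[:, selection.indices, :]
    if _rigid_drift(coords) > drift_tolerance:
        warnings.warn(
            "segment shows net rigid drift; superpose frames before PCA"
        )
    n_frames, n_atoms, _ = coords.shape
    flat = coords.reshape(n_frames, 3 * n_atoms)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / n_frames
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    total = eigvals.sum()
    dim = 3 * n_atoms
    if total <= 0:
        k = min(k_min, dim)
    else:
        cum = np.cumsum(eigvals) / total
        k_frac = int(np.searchsorted(cum, min_fraction - 1e-12) + 1)
        k = min(dim, max(k_min, k_frac))
    fraction = float(eigvals[:k].sum() / total) if total > 0 else 1.0

    subspace = EssentialSubspace(
        eigenvalues=eigvals,
        eigenvectors=eigvecs[:, :k],
        K=k,
        fraction_displacement=fraction,
        atom_indices=selection.indices.copy(),
        segment_id=segment_id,
    )
    slices = eigvecs[:, :k].reshape(n_atoms, 3, k).transpose(0, 2, 1)
    if weighting == "sqrt_lambda":
        slices = slices * np.sqrt(eigvals[:k])[np.newaxis, :, np.newaxis]
    coords_out = AtomEssentialCoordinates(
        eps=slices,
        atom_indices=selection.indices.copy(),
        weighting=weighting,
        segment_id=segment_id,
    )
    return subspace, coords_out


def flexibility_profile(
    segment_coords: list[AtomEssentialCoordinates],
    calpha_selection: AtomSelection,
    trajectory: Trajectory | None = None,
) -> pd.DataFrame:
    """Per-residue flexibility F, averaged over segments.

    ``F_i = ||eps_i - mean over Calpha eps||`` in 3K-space.  Returns a
    frame with res_id/res_name (when a trajectory supplies the topology),
    F_mean and the across-segment standard deviation F_sd.
    """
    if len(calpha_selection) == 0:
        raise ValueError("empty Calpha selection")
    if not segment_coords:
        raise ValueError("no segments supplied")
    per_segment = []
    for coords in segment_coords:
        rows = coords.rows_for(calpha_selection)
        flat = coords.flat[rows]
        centroid = flat.mean(axis=0)
        per_segment.append(np.linalg.norm(flat - centroid, axis=1))
    values = np.stack(per_segment)
    out = {
        "F_mean": values.mean(axis=0),
        "F_sd": values.std(axis=0, ddof=0),
    }
    if trajectory is not None:
        idx = calpha_selection.indices
        out = {
            "res_id": trajectory.topology.res_id[idx],
            "res_name": trajectory.topology.res_name[idx],
            **out,
        }
    return pd.DataFrame(out)


def correlation_descriptor(
    coords: AtomEssentialCoordinates,
    atoms_a: AtomSelection,
    atoms_b: AtomSelection,
) -> np.ndarray:
    """Matrix d[i, j] of 3K-space distances between two atom sets.

    d is a metric: zero on the diagonal of a self-comparison, symmetric,
    and satisfying the triangle inequality.
    """
    if len(atoms_a) == 0 or len(atoms_b) == 0:
        raise ValueError("empty selection")
    rows_a = coords.rows_for(atoms_a)
    rows_b = coords.rows_for(atoms_b)
    return cdist(coords.flat[rows_a], coords.flat[rows_b])


def residue_correlation(
    segment_coords: list[AtomEssentialCoordinates],
    probe_atom: int,
    dna_selection: AtomSelection,
    trajectory: Trajectory,
) -> pd.DataFrame:
    """Correlation descriptor between one probe atom and every DNA residue.

    For each DNA residue the minimum d over its atoms is taken (the
    strongest coupling), then averaged across segments.  Returns a frame
    with chain, res_id, d_mean, d_sd and the contact atom name realizing
    the per-residue minimum in the first segment.
    """
    top = trajectory.topology
    if len(dna_selection) == 0:
        raise ValueError("empty DNA selection")
    probe_sel = AtomSelection(np.array([probe_atom]), top.n_atoms)
    residues: dict[tuple[str, int], np.ndarray] = {}
    for g in dna_selection.indices:
        key = (str(top.chain_id[g]), int(top.res_id[g]))
        residues.setdefault(key, [])
        residues[key].append(int(g))

    records = []
    for (chain, res_id), atom_list in residues.items():
        atoms = AtomSelection(np.array(atom_list), top.n_atoms)
        per_segment = []
        contact = None
        for coords in segment_coords:
            d = correlation_descriptor(coords, probe_sel, atoms)[0]
            per_segment.append(d.min())
            if contact is None:
                contact = top.atom_name[atom_list[int(np.argmin(d))]]
        vals = np.array(per_segment)
        records.append({
            "chain": chain, "res_id": res_id,
            "d_mean": vals.mean(), "d_sd": vals.std(ddof=0),
            "contact_atom": contact,
        })
    records.sort(key=lambda r: (r["chain"], r["res_id"]))
    return pd.DataFrame(records)
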