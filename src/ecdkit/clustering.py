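"""Average-linkage RMSD conformational clustering and model selection.

Frames are fitted once on Calpha atoms, an all-atom RMSD matrix over the
interface selection is built without re-fitting, and agglomerative
average-linkage clusterings are cut at every candidate count (default
2-20).  Two complementary metrics pick the count: the Davies-Bouldin
index (lower is better; adequate clusterings appear as local minima) and
the elbow criterion (fraction of variance explained, SSR/SST, which
plateaus past the optimal count).  The selected count is the largest DBI
local minimum beyond the variance plateau; cluster representatives are
medoids (smallest mean RMSD to co-members).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .trajectory_io import AtomSelection, Trajectory, superpose

__all__ = [
    "ClusteringResult",
    "pairwise_rmsd_matrix",
    "average_linkage",
    "davies_bouldin",
    "elbow_curve",
    "plateau_count",
    "select_cluster_count",
    "extract_centroids",
    "run_clustering",
]

DEFAULT_COUNTS = range(2, 21)


def pairwise_rmsd_matrix(
    traj: Trajectory,
    fit_selection: AtomSelection,
    rmsd_selection: AtomSelection,
    reference_frame: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD over ``rmsd_selection``.

    All frames are first superposed on ``fit_selection`` against a common
    reference (first frame by default); the RMSD between frame pairs is
    then computed WITHOUT re-fitting, per the fit-once protocol.
    """
    if len(fit_selection) == 0 or len(rmsd_selection) == 0:
        raise ValueError("empty selection")
    ref = reference_frame if reference_frame is not None \
        else traj.coordinates[0]
    fitted = superpose(traj, ref, fit_selection)
    sub = fitted.coordinates[:, rmsd_selection.indices, :]
    n_frames, m, _ = sub.shape
    flat = sub.reshape(n_frames, 3 * m)
    # after a shared fit, pair RMSD is the Euclidean distance / sqrt(m)
    from scipy.spatial.distance import pdist

    mat = squareform(pdist(flat)) / np.sqrt(m)
    return mat


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(matrix) > 1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    return matrix


def average_linkage(matrix: np.ndarray, c: int) -> np.ndarray:
    """Cut an average-linkage (UPGMA) dendrogram at ``c`` clusters.

    Labels are integers in [0, c), renumbered by first appearance so the
    result is deterministic.
    """
    matrix = _check_matrix(matrix)
    n = matrix.shape[0]
    if c > n:
        raise ValueError(f"requested {c} clusters from {n} frames")
    if c < 1:
        raise ValueError("cluster count must be >= 1")
    if c == n:
        return np.arange(n)
    z = linkage(squareform(matrix, checks=False), method="average")
    raw = fcluster(z, t=c, criterion="maxclust")
    # renumber by first appearance
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    return labels


def _medoid(matrix: np.ndarray, members: np.ndarray) -> int:
    """Member with smallest mean distance to co-members; ties -> smallest
    frame index (argmin returns the first minimum)."""
    sub = matrix[np.ix_(members, members)]
    return int(members[np.argmin(sub.mean(axis=1))])


def davies_bouldin(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index in RMSD space with medoids as centers.

    ``DBI = (1/c) sum_i max_{j!=i} (S_i + S_j) / M_ij`` where S is the
    mean member-to-medoid distance and M the medoid separation.  Lower is
    better.  Coincident medoids give ``inf``.
    """
    matrix = _check_matrix(matrix)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("DBI needs at least two clusters")
    medoids = []
    scatter = []
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        m = _medoid(matrix, members)
        medoids.append(m)
        scatter.append(matrix[m, members].mean())
    total = 0.0
    for i in range(len(clusters)):
        worst = 0.0
        for j in range(len(clusters)):
            if i == j:
                continue
            sep = matrix[medoids[i], medoids[j]]
            if sep == 0.0:
                worst = np.inf
                break
            worst = max(worst, (scatter[i] + scatter[j]) / sep)
        total += worst
    return float(total / len(clusters))


def _pairwise_wss(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squares from pairwise distances.

    For Euclidean distances (which shared-fit RMSD matrices are, up to
    1/sqrt(m)) this equals the centroid-based sum of squares:
    ``sum_c (1/(2 n_c)) sum_{i,j in c} d_ij^2``.
    """
    wss = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        sub = matrix[np.ix_(members, members)]
        wss += (sub ** 2).sum() / (2.0 * len(members))
    return wss


def elbow_curve(matrix: np.ndarray,
                labels_per_count: dict[int, np.ndarray]) -> dict[int, float]:
    """SSR/SST (fraction of variance explained) for each cluster count."""
    matrix = _check_matrix(matrix)
    n = matrix.shape[0]
    sst = (matrix ** 2).sum() / (2.0 * n)
    out: dict[int, float] = {}
    for count, labels in sorted(labels_per_count.items()):
        if sst == 0.0:
            out[count] = 1.0
            continue
        ssr = sst - _pairwise_wss(matrix, np.asarray(labels))
        out[count] = float(min(max(ssr / sst, 0.0), 1.0))
    return out


def plateau_count(percent_variance: dict[int, float],
                  threshold: float = 0.01) -> int:
    """Smallest count after which every marginal gain is below threshold.

    ``threshold`` is in variance fraction units (0.01 = one percentage
    point per added cluster).
    """
    counts = sorted(percent_variance)
    if len(counts) < 2:
        return counts[0] if counts else 0
    gains = {
        c2: percent_variance[c2] - percent_variance[c1]
        for c1, c2 in zip(counts, counts[1:])
    }
    for i, c in enumerate(counts):
        later = counts[i + 1:]
        if all(gains[c2] < threshold for c2 in later):
            return c
    return counts[-1]


def _local_minima(counts: list[int], values: list[float]) -> list[int]:
    minima = []
    for i in range(1, len(counts) - 1):
        if values[i] < values[i - 1] and values[i] < values[i + 1]:
            minima.append(counts[i])
    return minima


def select_cluster_count(
    dbi_curve: dict[int, float],
    percent_variance_curve: dict[int, float],
    plateau_threshold: float = 0.01,
) -> int:
    """Pick the cluster count from the DBI and elbow curves.

    Adequate clusterings appear as DBI local minima; counts at or below
    the variance plateau under-resolve the data.  The rule returns the
    largest DBI local minimum strictly greater than the plateau count and
    falls back to the global DBI minimum (with a warning) if none
    qualifies.
    """
    counts = sorted(dbi_curve)
    values = [dbi_curve[c] for c in counts]
    plateau = plateau_count(percent_variance_curve, plateau_threshold)
    minima = _local_minima(counts, values)
    qualifying = [c for c in minima if c > plateau]
    if qualifying:
        return max(qualifying)
    fallback = counts[int(np.argmin(values))]
    warnings.warn(
        f"no DBI local minimum beyond the variance plateau ({plateau}); "
        f"falling back to the global DBI minimum ({fallback})"
    )
    return fallback


def extract_centroids(matrix: np.ndarray,
                      labels: np.ndarray) -> np.ndarray:
    """Medoid frame index per cluster, ordered by cluster label."""
    matrix = _check_matrix(matrix)
    labels = np.asarray(labels)
    return np.array([
        _medoid(matrix, np.flatnonzero(labels == c))
        for c in np.unique(labels)
    ])


@dataclass
class ClusteringResult:
    """All candidate clusterings plus curves and the selected count."""

    labels_per_count: dict[int, np.ndarray]
    dbi_curve: dict[int, float]
    percent_variance_curve: dict[int, float]
    selected_count: int
    centroid_frames: np.ndarray
    populations: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def labels(self) -> np.ndarray:
        return self.labels_per_count[self.selected_count]


def run_clustering(
    matrix: np.ndarray,
    counts: range | list[int] = DEFAULT_COUNTS,
    plateau_threshold: float = 0.01,
) -> ClusteringResult:
    """Cluster at every candidate count and select one (end-to-end)."""
    matrix = _check_matrix(matrix)
    n = matrix.shape[0]
    counts = [c for c in counts if c <= n]
    if not counts:
        raise ValueError("no feasible cluster counts")
    labels_per_count = {c: average_linkage(matrix, c) for c in counts}
    dbi = {c: davies_bouldin(matrix, labels_per_count[c]) for c in counts}
    pv = elbow_curve(matrix, labels_per_count)
    selected = select_cluster_count(dbi, pv, plateau_threshold)
    labels = labels_per_count[selected]
    centroids = extract_centroids(matrix, labels)
    pops = np.bincount(labels, minlength=selected) / len(labels)
    return ClusteringResult(
        labels_per_count=labels_per_count,
        dbi_curve=dbi,
        percent_variance_curve=pv,
        selected_count=selected,
        centroid_frames=centroids,
        populations=pops,
    )
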