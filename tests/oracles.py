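"""Independent brute-force reference implementations.

Everything here is deliberately naive — explicit loops, direct formulas,
exhaustive search — and shares no code path with the package.  These are
the ground truth the implementation is checked against on tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# covariance / essential dynamics
# ---------------------------------------------------------------------------

def sample_covariance(flat: np.ndarray) -> np.ndarray:
    """Biased sample covariance via an explicit double loop (small inputs)."""
    n_frames, dim = flat.shape
    mean = np.array([flat[:, a].sum() / n_frames for a in range(dim)])
    cov = np.zeros((dim, dim))
    for t in range(n_frames):
        d = flat[t] - mean
        for a in range(dim):
            for b in range(dim):
                cov[a, b] += d[a] * d[b]
    return cov / n_frames


def leading_eigenpairs(cov: np.ndarray, k: int):
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order][:k], vecs[:, order][:, :k]


def essential_descriptors(coords: np.ndarray, k_min: int,
                          min_fraction: float):
    """One-shot direct computation of eigenpairs, flexibility F and the
    pairwise correlation matrix d (sqrt-eigenvalue weighting)."""
    n_frames, n_atoms, _ = coords.shape
    flat = coords.reshape(n_frames, 3 * n_atoms)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = np.zeros((3 * n_atoms, 3 * n_atoms))
    for t in range(n_frames):
        cov += np.outer(centered[t], centered[t])
    cov /= n_frames
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    k = k_min
    if total > 0:
        cum = 0.0
        for i, v in enumerate(vals, start=1):
            cum += v
            if cum / total >= min_fraction:
                k = max(k_min, i)
                break
    k = min(k, 3 * n_atoms)
    # per-atom essential coordinates, sqrt(lambda)-scaled
    eps = np.zeros((n_atoms, 3 * k))
    for i in range(n_atoms):
        parts = []
        for mode in range(k):
            parts.append(np.sqrt(vals[mode]) * vecs[3 * i:3 * i + 3, mode])
        eps[i] = np.concatenate(parts)
    centroid = eps.mean(axis=0)
    flexibility = np.array(
        [np.linalg.norm(eps[i] - centroid) for i in range(n_atoms)])
    d = np.zeros((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(n_atoms):
            d[i, j] = np.linalg.norm(eps[i] - eps[j])
    return vals, vecs[:, :k], k, flexibility, d


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def grid_fit_rmsd(ref: np.ndarray, mobile: np.ndarray) -> float:
    """Minimum RMSD over rotations: coarse Euler grid + simplex refinement.

    Independent of the closed-form Kabsch solution used by the package.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)

    def cost(angles):
        rot = Rotation.from_euler("zyz", angles)
        return np.sqrt(np.mean(
            np.sum((rot.apply(mob_c) - ref_c) ** 2, axis=1)))

    best = None
    step = np.pi / 9  # 20 degree grid
    for a in np.arange(0, 2 * np.pi, step):
        for b in np.arange(0, np.pi + 1e-9, step):
            for c in np.arange(0, 2 * np.pi, step):
                v = cost((a, b, c))
                if best is None or v < best[0]:
                    best = (v, (a, b, c))
    res = minimize(cost, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14,
                            "maxiter": 5000})
    return float(min(best[0], res.fun))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def brute_force_average_linkage(matrix: np.ndarray) -> dict[int, list[int]]:
    """Naive agglomerative average linkage; labels for every cut level.

    Merges the cluster pair with smallest mean inter-cluster distance;
    ties broken by smallest member indices.  Returns {count: labels}.
    """
    n = matrix.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    out: dict[int, list[int]] = {}

    def record():
        labels = [0] * n
        order = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
        for new_label, c in enumerate(order):
            for i in clusters[c]:
                labels[i] = new_label
        out[len(clusters)] = labels

    record()
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([matrix[i, j] for i in clusters[a]
                            for j in clusters[b]])
            key = (dist, min(clusters[a]), min(clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        record()
    return out


def direct_dbi(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin with medoid centers, straight from the formula."""
    clusters = sorted(set(labels))
    medoids, scatters = [], []
    for c in clusters:
        members = [i for i in range(len(labels)) if labels[i] == c]
        means = [np.mean([matrix[m, j] for j in members]) for m in members]
        medoid = members[int(np.argmin(means))]
        medoids.append(medoid)
        scatters.append(np.mean([matrix[medoid, j] for j in members]))
    terms = []
    for i in range(len(clusters)):
        ratios = []
        for j in range(len(clusters)):
            if i == j:
                continue
            sep = matrix[medoids[i], medoids[j]]
            ratios.append(np.inf if sep == 0
                          else (scatters[i] + scatters[j]) / sep)
        terms.append(max(ratios))
    return float(np.mean(terms))


def exhaustive_medoid(matrix: np.ndarray, members: list[int]) -> int:
    best = None
    for m in members:
        mean = np.mean([matrix[m, j] for j in members])
        if best is None or mean < best[0] - 1e-15:
            best = (mean, m)
    return best[1]


# ---------------------------------------------------------------------------
# energies and surface area
# ---------------------------------------------------------------------------

def pairwise_energy_loops(coords, charges, sigmas, epsilons,
                          group_a, group_b, k_coulomb=332.0637,
                          dielectric=1.0):
    """Double-loop Coulomb + Lennard-Jones cross-interaction energies."""
    e_ele = 0.0
    e_vdw = 0.0
    for i in group_a:
        for j in group_b:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            e_ele += k_coulomb * charges[i] * charges[j] / (dielectric * r)
            sig = 0.5 * (sigmas[i] + sigmas[j])
            eps = np.sqrt(epsilons[i] * epsilons[j])
            e_vdw += 4.0 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    return e_ele, e_vdw


def sphere_sasa(radius: float, probe: float = 1.4) -> float:
    return 4.0 * np.pi * (radius + probe) ** 2


def two_sphere_sasa(r1: float, r2: float, d: float,
                    probe: float = 1.4) -> float:
    """Analytic accessible area of two intersecting spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return sphere_sasa(r1, probe) + sphere_sasa(r2, probe)
    if d + min(R1, R2) <= max(R1, R2):
        return sphere_sasa(max(r1, r2), probe)  # one engulfs the other
    # spherical-cap heights buried on each sphere
    h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
    h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
    return (4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1) \
        + (4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2)
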