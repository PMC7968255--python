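"""Cluster-based permutation inference on voxel x frequency maps.

Cell-level statistics (paired t for the condition contrast; Pearson r
converted to t for the across-subject brain-cochlea correlation) are
thresholded at a parametric cluster-forming level, connected components are
formed over a spatio-spectral neighborhood (spatial lattice neighbors at the
same frequency plus the same voxel at adjacent frequency bins; no diagonal
space-frequency edges), and each cluster's mass (sum of t) is referred to
the permutation distribution of the maximal cluster mass (per-subject sign
flips of condition differences, or permutation of the cochlear vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps


@dataclass
class AdjacencyGraph:
    """Spatio-spectral connectivity over a regular voxel lattice.

    Spatial neighbors are lattice sites within one step along each axis
    (26-neighborhood); the frequency rule couples the same voxel at adjacent
    bins only.
    """

    grid_shape: tuple[int, int, int]

    def structure(self) -> np.ndarray:
        s = np.zeros((3, 3, 3, 3), dtype=bool)
        s[:, :, :, 1] = True  # all spatial neighbors at the same frequency
        s[1, 1, 1, 0] = s[1, 1, 1, 2] = True  # same voxel, adjacent frequency
        return s

    def label(self, mask: np.ndarray):
        """Connected components of a (n_voxels, n_freqs) boolean mask."""
        n_f = mask.shape[1]
        cube = mask.reshape(self.grid_shape + (n_f,))
        labels, n = ndimage.label(cube, structure=self.structure())
        return labels.reshape(mask.shape), n

    def voxel_neighbors(self, i: int) -> np.ndarray:
        """Flat indices of spatial neighbors of voxel i (no self edge)."""
        pos = np.array(np.unravel_index(i, self.grid_shape))
        deltas = np.stack(np.meshgrid(*[[-1, 0, 1]] * 3, indexing="ij"), -1).reshape(-1, 3)
        deltas = deltas[np.any(deltas != 0, axis=1)]
        cand = pos + deltas
        ok = np.all((cand >= 0) & (cand < np.array(self.grid_shape)), axis=1)
        return np.ravel_multi_index(cand[ok].T, self.grid_shape)


def lattice_adjacency(grid_shape) -> AdjacencyGraph:
    return AdjacencyGraph(tuple(grid_shape))


@dataclass
class Cluster:
    cells: np.ndarray  # (n_cells, 2) of (voxel, freq-bin) indices
    mass: float  # sum of the cell statistic, sign-consistent
    sign: int
    p_mc: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_forming_alpha: float
    observed_stat_map: np.ndarray  # (n_voxels, n_freqs)
    freqs: np.ndarray | None = None
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def min_p(self) -> float:
        return min((c.p_mc for c in self.clusters), default=1.0)


def _clusters_from_map(t_map: np.ndarray, threshold: float,
                       adjacency: AdjacencyGraph):
    """Sign-separated clusters: list of (cell-index array, mass, sign)."""
    out = []
    for sign in (1, -1):
        mask = (sign * t_map) > threshold
        if not mask.any():
            continue
        labels, n = adjacency.label(mask)
        if n == 0:
            continue
        sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
        for lab in range(1, n + 1):
            cells = np.argwhere(labels == lab)
            out.append((cells, float(sums[lab - 1]), sign))
    return out


def _max_cluster_mass(t_map: np.ndarray, threshold: float,
                      adjacency: AdjacencyGraph) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = (sign * t_map) > threshold
        if not mask.any():
            continue
        labels, n = adjacency.label(mask)
        if n:
            sums = ndimage.sum_labels(np.abs(t_map), labels,
                                      index=np.arange(1, n + 1))
            best = max(best, float(sums.max()))
    return best


def _paired_t_maps(flat_diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for many sign-flip patterns at once.

    ``flat_diffs`` is subjects x cells; ``signs`` is patterns x subjects of
    +/-1.  Sign flips leave each cell's mean square unchanged, so the
    per-pattern variance comes from the flipped mean alone.
    """
    n = flat_diffs.shape[0]
    means = signs @ flat_diffs / n
    msq = (flat_diffs ** 2).mean(axis=0)
    var = (msq[None, :] - means ** 2) * (n / (n - 1))
    var = np.maximum(var, np.finfo(float).tiny)
    return means / np.sqrt(var / n)


def condition_cluster_test(power: np.ndarray, adjacency: AdjacencyGraph,
                           n_perm: int = 1000, forming_alpha: float = 0.05,
                           seed: int | None = None,
                           freqs: np.ndarray | None = None) -> ClusterResult:
    """Paired condition contrast (first condition minus second) with a
    sign-flip max-cluster-mass permutation null.

    ``power`` is subjects x voxels x freqs x 2; the caller restricts the
    frequency axis (3-25 Hz in the standard analysis) before entry.
    p_mc = (1 + #{null >= observed}) / (1 + n_perm).
    """
    n_subj = power.shape[0]
    if n_subj < 6:
        raise ValueError("need at least 6 subjects")
    diffs = power[..., 0] - power[..., 1]
    shape = diffs.shape[1:]
    flat = diffs.reshape(n_subj, -1)
    threshold = float(sps.t.ppf(1 - forming_alpha / 2, n_subj - 1))

    t_obs = _paired_t_maps(flat, np.ones((1, n_subj)))[0].reshape(shape)
    observed = _clusters_from_map(t_obs, threshold, adjacency)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    t_perm = _paired_t_maps(flat, signs)
    null_max = np.array([_max_cluster_mass(t_perm[i].reshape(shape), threshold,
                                           adjacency) for i in range(n_perm)])

    clusters = [Cluster(cells, mass, sign,
                        float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)))
                for cells, mass, sign in observed]
    clusters.sort(key=lambda c: c.p_mc)
    return ClusterResult(clusters, n_perm, forming_alpha, t_obs, freqs, null_max)


def _corr_t_maps(brain_flat: np.ndarray, z_vectors: np.ndarray) -> np.ndarray:
    """Pearson-r-derived t maps for many orderings of the cochlear vector.

    ``brain_flat`` is subjects x cells; ``z_vectors`` is patterns x subjects,
    each row the standardized cochlear vector in some subject order.
    """
    n = brain_flat.shape[0]
    b = brain_flat - brain_flat.mean(axis=0)
    sd = b.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    r = (z_vectors @ b) / (n * sd[None, :])
    r = np.clip(r, -0.999999, 0.999999)
    return r * np.sqrt((n - 2) / (1 - r ** 2))


def correlation_cluster_test(brain_ami: np.ndarray, ooa_ami: np.ndarray,
                             adjacency: AdjacencyGraph, n_perm: int = 1000,
                             forming_alpha: float = 0.05,
                             seed: int | None = None,
                             freqs: np.ndarray | None = None) -> ClusterResult:
    """Across-subject correlation of brain AMI maps with the cochlear AMI.

    Pearson r per (voxel, freq) cell, converted to t with n-2 df; the null
    permutes the subject order of the cochlear vector, preserving the brain
    maps' spatial covariance.
    """
    brain = np.asarray(brain_ami, dtype=float)
    ooa = np.asarray(ooa_ami, dtype=float)
    n_subj = brain.shape[0]
    if ooa.size != n_subj or n_subj < 6:
        raise ValueError("need a cochlear value per subject, n >= 6")
    if ooa.std() == 0:
        raise ValueError("cochlear AMI vector has zero variance")
    shape = brain.shape[1:]
    flat = brain.reshape(n_subj, -1)
    z = (ooa - ooa.mean()) / ooa.std()
    threshold = float(sps.t.ppf(1 - forming_alpha / 2, n_subj - 2))

    t_obs = _corr_t_maps(flat, z[None, :])[0].reshape(shape)
    observed = _clusters_from_map(t_obs, threshold, adjacency)

    rng = np.random.default_rng(seed)
    z_perm = np.stack([z[rng.permutation(n_subj)] for _ in range(n_perm)])
    t_perm = _corr_t_maps(flat, z_perm)
    null_max = np.array([_max_cluster_mass(t_perm[i].reshape(shape), threshold,
                                           adjacency) for i in range(n_perm)])

    clusters = [Cluster(cells, mass, sign,
                        float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)))
                for cells, mass, sign in observed]
    clusters.sort(key=lambda c: c.p_mc)
    return ClusterResult(clusters, n_perm, forming_alpha, t_obs, freqs, null_max)


def cluster_profile(result: ClusterResult, cluster_index: int = 0) -> np.ndarray:
    """Member-voxel counts per frequency bin for one cluster (default: the
    most significant).  Empty result -> empty profile."""
    if not result.clusters:
        return np.empty(0, dtype=int)
    n_f = result.observed_stat_map.shape[1]
    counts = np.zeros(n_f, dtype=int)
    cells = result.clusters[cluster_index].cells
    for _, f in cells:
        counts[f] += 1
    return counts
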