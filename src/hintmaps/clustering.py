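"""Per-bin k-means clustering of interaction maps, singleton recovery,
Gaussian-weighted average maps/structures, exemplars and cluster summaries.

Maps in a chess-square/parse bin are clustered in the feature space given by
their rows of the pairwise similarity matrix.  Bins with four or fewer maps
are averaged as a single cluster.  Cluster averages weight each member by
w = exp(-d²/σ²) with d its feature-space distance to the centroid and
σ = d_max/8, d_max being the mean over the bin's clusters of each cluster's
maximum centroid distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .config import K_MAX, SMALL_BIN_MAX
from .conformation import BinKey
from .interaction_maps import InteractionMapSet
from .map_similarity import TransformedMap, similarity_matrix


@dataclass
class ClusterSolution:
    bin_key: BinKey | None
    assignments: np.ndarray          # map index -> cluster id (0..k_used-1)
    features: np.ndarray             # n_maps × n_features (similarity rows)
    centroids: np.ndarray            # k_used × n_features
    k_used: int

    @property
    def n_maps(self) -> int:
        return len(self.assignments)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)

    def distances(self, cluster_id: int) -> np.ndarray:
        m = self.members(cluster_id)
        return np.linalg.norm(
            self.features[m] - self.centroids[cluster_id], axis=1)

    def exemplar(self, cluster_id: int) -> int:
        """Member map index closest to the cluster centroid."""
        m = self.members(cluster_id)
        return int(m[np.argmin(self.distances(cluster_id))])

    def relabel(self, assignments: np.ndarray, centroids: np.ndarray) -> "ClusterSolution":
        return ClusterSolution(self.bin_key, assignments, self.features,
                               centroids, centroids.shape[0])


@dataclass
class ClusterSummary:
    bin_key: BinKey | None
    cluster_id: int
    name: int                          # exemplar map index (bold-number convention)
    n_members: int
    relative_fraction: float           # % of bin membership
    mean_sasa: float
    sd_sasa: float
    mean_lasa: float
    sd_lasa: float
    f_outside: float
    average_map: InteractionMapSet | None
    rmsd_heavy: float
    rmsd_all: float
    character: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_bin(maps: list[TransformedMap], residue_type: str, seed: int, *,
                k_max: dict | None = None, restarts: int = 50) -> ClusterSolution:
    """Cluster a bin's maps; bins of ≤ 4 maps become a single cluster."""
    if not maps:
        raise ValueError("cannot cluster an empty bin")
    k_table = k_max or K_MAX
    bin_key = maps[0].bin_key
    features = similarity_matrix(maps)
    n = len(maps)
    if n <= SMALL_BIN_MAX:
        assignments = np.zeros(n, dtype=int)
        centroids = features.mean(axis=0, keepdims=True)
        return ClusterSolution(bin_key, assignments, features, centroids, 1)
    k = min(k_table[residue_type], n)
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=int(seed) % (2 ** 31))
    labels = km.fit_predict(features)
    # drop empty clusters (possible with duplicate points), compact labels
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    assignments = np.array([remap[x] for x in labels])
    centroids = np.stack([features[assignments == c].mean(axis=0)
                          for c in range(len(used))])
    return ClusterSolution(bin_key, assignments, features, centroids, len(used))


def recover_singletons(solution: ClusterSolution,
                       threshold_sd: float = 3.0) -> ClusterSolution:
    """Split extreme within-cluster outliers into singleton clusters.

    A member is an outlier when its centroid distance exceeds
    mean + threshold_sd · sd of its cluster's distances; surviving members
    are re-assigned to the nearest recomputed centroid.
    """
    outliers: list[int] = []
    for c in range(solution.k_used):
        m = solution.members(c)
        if m.size < 3:
            continue
        d = solution.distances(c)
        cut = d.mean() + threshold_sd * d.std()
        outliers.extend(int(i) for i, di in zip(m, d) if di > cut)
    if not outliers:
        return solution
    keep = np.setdiff1d(np.arange(solution.n_maps), outliers)
    centroids = []
    for c in range(solution.k_used):
        m = np.intersect1d(solution.members(c), keep)
        if m.size:
            centroids.append(solution.features[m].mean(axis=0))
    centroids = np.stack(centroids)
    assignments = np.empty(solution.n_maps, dtype=int)
    for i in keep:
        assignments[i] = int(np.argmin(
            np.linalg.norm(centroids - solution.features[i], axis=1)))
    next_id = centroids.shape[0]
    single_centroids = []
    for i in outliers:
        assignments[i] = next_id
        single_centroids.append(solution.features[i])
        next_id += 1
    all_centroids = np.vstack([centroids] + [np.stack(single_centroids)])
    return solution.relabel(assignments, all_centroids)


def apply_solution(solution: ClusterSolution,
                   paired_maps: list[TransformedMap]) -> ClusterSolution:
    """Carry one dataset's memberships onto a paired variant set (e.g. the
    mL solution applied residue-for-residue to the mN maps)."""
    if len(paired_maps) != solution.n_maps:
        raise ValueError("paired set size differs from the clustered set")
    features = similarity_matrix(paired_maps)
    centroids = np.stack([features[solution.members(c)].mean(axis=0)
                          for c in range(solution.k_used)])
    return ClusterSolution(paired_maps[0].bin_key, solution.assignments.copy(),
                           features, centroids, solution.k_used)


# ---------------------------------------------------------------------------
# weighted averages
# ---------------------------------------------------------------------------

def bin_sigma(solution: ClusterSolution) -> float:
    """σ = d_max/8 where d_max is the mean over the bin's clusters of each
    cluster's maximum centroid distance."""
    maxima = [solution.distances(c).max() for c in range(solution.k_used)]
    return float(np.mean(maxima)) / 8.0


def gaussian_weights(distances: np.ndarray, sigma: float) -> np.ndarray:
    """w = exp(-d²/σ²); degenerate σ = 0 (all members at the centroid)
    falls back to flat weights."""
    distances = np.asarray(distances, dtype=float)
    if sigma <= 0:
        return np.ones_like(distances)
    return np.exp(-(distances ** 2) / sigma ** 2)


def weighted_average_map(members: list[InteractionMapSet],
                         distances: np.ndarray,
                         sigma: float) -> InteractionMapSet:
    if not members:
        raise ValueError("empty cluster")
    w = gaussian_weights(distances, sigma)
    total = w.sum()
    out = members[0].scale(w[0] / total)
    for mi, wi in zip(members[1:], w[1:]):
        out = out + mi.scale(wi / total)
    out.residue_id = "average"
    return out


def weighted_average_structure(member_coords: list[np.ndarray],
                               distances: np.ndarray,
                               sigma: float) -> np.ndarray:
    """Gaussian-weighted mean of atom positions (atoms matched by order;
    all members must share the atom list, in the canonical frame)."""
    w = gaussian_weights(distances, sigma)
    stack = np.stack(member_coords)           # n_members × n_atoms × 3
    return np.einsum("m,mij->ij", w, stack) / w.sum()


def cluster_rmsd(member_coords: list[np.ndarray],
                 average: np.ndarray) -> float:
    """Pooled RMSD of members against the average structure (no refit:
    members are already in the canonical frame)."""
    stack = np.stack(member_coords)
    d2 = ((stack - average[None]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.mean()))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_cluster(solution: ClusterSolution, cluster_id: int, *,
                      raw_maps: list[InteractionMapSet],
                      accessibility=None,
                      heavy_coords: list[np.ndarray] | None = None,
                      all_coords: list[np.ndarray] | None = None,
                      sigma: float | None = None) -> ClusterSummary:
    """Summary of one cluster: exemplar name, relative fraction, SASA/LASA
    statistics, weighted-average map and structure RMSDs.

    `accessibility` is a sequence of AccessibilityRecord aligned with the
    bin's map list; SASA statistics pool non-LASA members and LASA statistics
    LASA members (a residue's area is all-or-nothing reclassified).
    """
    from .accessibility import f_outside as _f_outside

    members = solution.members(cluster_id)
    dists = solution.distances(cluster_id)
    if sigma is None:
        sigma = bin_sigma(solution)
    avg_map = weighted_average_map([raw_maps[i] for i in members], dists, sigma)

    mean_sasa = sd_sasa = mean_lasa = sd_lasa = float("nan")
    f_out = float("nan")
    if accessibility is not None:
        recs = [accessibility[i] for i in members]
        sasa_vals = np.array([r.sasa for r in recs if not r.is_lasa])
        lasa_vals = np.array([r.sasa for r in recs if r.is_lasa])
        if sasa_vals.size:
            mean_sasa, sd_sasa = float(sasa_vals.mean()), float(sasa_vals.std())
        if lasa_vals.size:
            mean_lasa, sd_lasa = float(lasa_vals.mean()), float(lasa_vals.std())
        f_out = _f_outside(recs)

    rmsd_heavy = rmsd_all = float("nan")
    if heavy_coords is not None:
        sub = [heavy_coords[i] for i in members]
        rmsd_heavy = cluster_rmsd(sub, weighted_average_structure(sub, dists, sigma))
    if all_coords is not None:
        sub = [all_coords[i] for i in members]
        rmsd_all = cluster_rmsd(sub, weighted_average_structure(sub, dists, sigma))

    return ClusterSummary(
        bin_key=solution.bin_key, cluster_id=cluster_id,
        name=solution.exemplar(cluster_id), n_members=int(members.size),
        relative_fraction=100.0 * members.size / solution.n_maps,
        mean_sasa=mean_sasa, sd_sasa=sd_sasa,
        mean_lasa=mean_lasa, sd_lasa=sd_lasa,
        f_outside=f_out, average_map=avg_map,
        rmsd_heavy=rmsd_heavy, rmsd_all=rmsd_all,
        character=avg_map.character_fractions(),
    )


def summarize_bin(solution: ClusterSolution, **kwargs) -> list[ClusterSummary]:
    sigma = kwargs.pop("sigma", None) or bin_sigma(solution)
    return [summarize_cluster(solution, c, sigma=sigma, **kwargs)
            for c in range(solution.k_used)]
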