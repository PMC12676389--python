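"""Gold-nanoparticle cluster-size statistics on membrane point patterns.

A cluster is a single-linkage connected component: two particles belong to
the same cluster iff a chain of pairwise distances <= linkage_radius connects
them (singletons allowed). Cluster sizes are pooled across images within a
condition and compared between conditions with a two-sided Mann-Whitney U
test (Kolmogorov-Smirnov optional).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import ClusterStats, GoldParticleSet


def cluster_particles(points: np.ndarray, linkage_radius: float) -> list[np.ndarray]:
    """Single-linkage connected components at the given radius.

    Returns a list of index arrays, one per cluster, covering every particle
    exactly once. Empty input yields an empty list.
    """
    if linkage_radius <= 0:
        raise ValueError("linkage_radius must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=linkage_radius, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return [np.nonzero(labels == c)[0] for c in range(n_comp)]


def cluster_sizes(points: np.ndarray, linkage_radius: float) -> list[int]:
    return sorted(len(c) for c in cluster_particles(points, linkage_radius))


def cluster_size_stats(
    sets: Sequence[GoldParticleSet], linkage_radius: float
) -> dict[str, ClusterStats]:
    """Per-condition pooled cluster-size statistics with per-image breakdown."""
    by_condition: dict[str, list[GoldParticleSet]] = {}
    for s in sets:
        by_condition.setdefault(s.condition_label, []).append(s)
    out: dict[str, ClusterStats] = {}
    for condition, images in by_condition.items():
        pooled: list[int] = []
        per_image: dict[str, list[int]] = {}
        for img in images:
            sizes = cluster_sizes(img.points, linkage_radius)
            per_image[img.image_id] = sizes
            pooled.extend(sizes)
        out[condition] = ClusterStats(
            condition_label=condition,
            cluster_sizes=pooled,
            linkage_radius=linkage_radius,
            n_images=len(images),
            per_image_sizes=per_image,
        )
    return out


def compare_conditions(
    sizes_a: Sequence[int],
    sizes_b: Sequence[int],
    test: str = "mannwhitney",
) -> tuple[float, float, bool]:
    """Two-sided comparison of cluster-size samples.

    Mann-Whitney U uses the exact null for small tie-free samples and the
    tie-corrected normal approximation otherwise. Returns
    (statistic, p_value, zero_variance_flag); identical constant samples give
    p = 1 with the flag set.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return float(a.size * b.size / 2.0), 1.0, True
    if test == "mannwhitney":
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    elif test == "ks":
        res = stats.ks_2samp(a, b, alternative="two-sided")
    else:
        raise ValueError("test must be 'mannwhitney' or 'ks'")
    return float(res.statistic), float(res.pvalue), False


def radius_sweep(
    points: np.ndarray, radii: Sequence[float]
) -> list[tuple[float, int, float]]:
    """Sensitivity of the clustering to the linkage radius.

    Returns (radius, n_clusters, mean cluster size) per radius; the number of
    clusters is non-increasing in the radius.
    """
    out = []
    for r in radii:
        sizes = cluster_sizes(points, r)
        mean = float(np.mean(sizes)) if sizes else 0.0
        out.append((float(r), len(sizes), mean))
    return out
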