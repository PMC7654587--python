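"""Clustering of layout ensembles and selection of the meaningful cluster.

Independent force-directed layouts of the same contact network land in
different basins: some capture the territory organization up to rigid
motion, others capture mirror-inverted orderings (center and periphery
swapped for some or all territories). Rather than averaging everything,
the models are K-means-clustered on their radial-distance profiles and
the cluster whose mean profile correlates most strongly (in absolute
value) with the PCA-inferred organizing property is selected.

Everything is deterministic: K-means uses a deterministic density-pair
initialization instead of random restarts, and ties break by documented
rules, so a fixed distance matrix always yields the same result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .hic_io import ChromProperties
from .network_ensemble import DistanceMatrix

__all__ = [
    "ClusterResult",
    "kmeans_deterministic",
    "detect_elbow",
    "choose_k",
    "select_cluster",
    "cluster_models",
]


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    centroids: np.ndarray | None = None
    inertia: float = np.nan
    inertia_curve: list[tuple[int, float]] = field(default_factory=list)
    silhouette_by_k: list[tuple[int, float]] = field(default_factory=list)
    elbow_k: int | None = None
    selected_cluster: int | None = None
    selected_models: np.ndarray | None = None
    selection_corr: float = np.nan
    cluster_corrs: dict[int, float] = field(default_factory=dict)


def _nazeer_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic initial centroids by growing dense point groups.

    Repeatedly: find the closest pair among unassigned points, grow that
    group by nearest unassigned neighbors to size n/k, use its mean as a
    centroid, and remove the group. Repeat k times.
    """
    n = X.shape[0]
    remaining = list(range(n))
    target = max(1, n // k)
    centroids = np.empty((k, X.shape[1]))
    for c in range(k):
        if len(remaining) == 1:
            centroids[c] = X[remaining[0]]
            continue
        pts = X[remaining]
        D = cdist(pts, pts)
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        group = {i, j}
        while len(group) < min(target, len(remaining)):
            dmin = np.min(D[list(group)], axis=0)
            dmin[list(group)] = np.inf
            group.add(int(np.argmin(dmin)))
        gidx = [remaining[g] for g in sorted(group)]
        centroids[c] = X[gidx].mean(axis=0)
        remaining = [r for r in remaining if r not in set(gidx)]
        if not remaining:
            remaining = list(range(n))  # degenerate: reuse pool
    return centroids


def kmeans_deterministic(
    X: np.ndarray | DistanceMatrix, k: int, max_iter: int = 300,
    tol: float = 1e-9,
) -> ClusterResult:
    """Lloyd's K-means from deterministic initial centroids.

    An empty cluster arising during iteration is re-seeded at the point
    farthest from its nearest centroid. Identical input always yields
    identical labels.
    """
    if isinstance(X, DistanceMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} points")
    centroids = X.mean(axis=0, keepdims=True) if k == 1 else _nazeer_init(X, k)
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        D = cdist(X, centroids)
        labels = np.argmin(D, axis=1)
        new_centroids = centroids.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centroids[c] = X[mask].mean(axis=0)
            else:
                far = int(np.argmax(np.min(D, axis=1)))
                new_centroids[c] = X[far]
                labels[far] = c
        shift = np.linalg.norm(new_centroids - centroids)
        centroids = new_centroids
        if shift < tol:
            break
    inertia = float(((X - centroids[labels]) ** 2).sum())
    return ClusterResult(labels=labels, k=k, centroids=centroids, inertia=inertia)


def detect_elbow(ks: np.ndarray, inertias: np.ndarray,
                 sensitivity: float = 1.0) -> int | None:
    """Kneedle-style knee of a decreasing convex curve.

    The curve is normalized to the unit square and flipped to concave
    increasing form; the knee is the maximum of the difference between
    the flipped curve and the diagonal, accepted when it exceeds the
    sensitivity-scaled mean x-spacing. Returns None when no knee stands
    out (featureless curve).
    """
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(inertias, dtype=float)
    if len(ks) < 3 or np.ptp(y) == 0:
        return None
    xn = (ks - ks.min()) / np.ptp(ks)
    yn = (y - y.min()) / np.ptp(y)
    diff = (1.0 - yn) - xn
    j = int(np.argmax(diff))
    threshold = sensitivity * np.mean(np.diff(xn))
    if diff[j] <= threshold:
        return None
    return int(ks[j])


def choose_k(
    D: np.ndarray | DistanceMatrix,
    k_range=range(2, 16),
    sensitivity: float = 1.0,
) -> ClusterResult:
    """Select the number of clusters by elbow + local silhouette search.

    The inertia-curve knee gives a candidate k; the final k maximizes the
    mean silhouette score over the knee and its two neighbors on each
    side (clipped to the range). Without a detectable knee, the
    silhouette argmax over the whole range is used.
    """
    if isinstance(D, DistanceMatrix):
        D = D.values
    D = np.asarray(D, dtype=float)
    ks = [k for k in k_range if 2 <= k <= D.shape[0] // 2]
    if len(ks) < 2:
        raise ValueError("k_range leaves fewer than two candidate k values")
    fits = {k: kmeans_deterministic(D, k) for k in ks}
    inertia_curve = [(k, fits[k].inertia) for k in ks]
    sil = {}
    for k in ks:
        labels = fits[k].labels
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(D, labels))
    elbow = detect_elbow(np.array(ks), np.array([i for _, i in inertia_curve]),
                         sensitivity)
    if elbow is None:
        warnings.warn("no knee detected in inertia curve; "
                      "falling back to global silhouette maximum")
        vicinity = ks
    else:
        vicinity = [k for k in ks if elbow - 2 <= k <= elbow + 2]
    best_k = max(vicinity, key=lambda k: (sil[k], -k))
    result = fits[best_k]
    result.inertia_curve = inertia_curve
    result.silhouette_by_k = sorted(sil.items())
    result.elbow_k = elbow
    return result


def select_cluster(
    result: ClusterResult,
    D: np.ndarray | DistanceMatrix,
    props: ChromProperties,
    inferred_type: str,
    chrom_order: list[str] | None = None,
    min_size: int = 5,
) -> ClusterResult:
    """Pick the cluster matching the inferred organization property.

    For each cluster, the mean radial profile over its models is
    correlated (Pearson) with gene density or chromosome length per the
    inferred type; the cluster with the largest |r| wins. The sign of r
    is reported, not corrected: a negative r flags a mirror-oriented
    cluster, which contact data alone cannot disambiguate. Ties break
    toward the larger cluster, then the lower cluster id. Clusters
    smaller than ``min_size`` are excluded.
    """
    if isinstance(D, DistanceMatrix):
        chrom_order = chrom_order or D.chrom_order
        D = D.values
    if chrom_order is None:
        raise ValueError("chrom_order required when D is a bare array")
    if inferred_type not in ("gene_density", "length"):
        raise ValueError("inferred_type must be 'gene_density' or 'length'")
    props = props.reindex(chrom_order)
    prop = props.gene_density if inferred_type == "gene_density" else props.length_bp

    corrs: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for c in np.unique(result.labels):
        mask = result.labels == c
        sizes[int(c)] = int(mask.sum())
        if mask.sum() < min_size:
            warnings.warn(f"cluster {c} has fewer than {min_size} models; excluded")
            continue
        mean_profile = D[mask].mean(axis=0)
        if np.std(mean_profile) == 0:
            corrs[int(c)] = 0.0
        else:
            corrs[int(c)] = float(stats.pearsonr(mean_profile, prop)[0])
    if not corrs:
        raise ValueError("no cluster meets the minimum size for selection")
    best = max(corrs, key=lambda c: (round(abs(corrs[c]), 12), sizes[c], -c))
    result.selected_cluster = int(best)
    result.selected_models = D[result.labels == best]
    result.selection_corr = corrs[best]
    result.cluster_corrs = corrs
    return result


def cluster_models(
    D: DistanceMatrix,
    props: ChromProperties,
    inferred_type: str,
    k_range=range(2, 16),
) -> ClusterResult:
    """choose_k then select_cluster, the full model-selection stage."""
    result = choose_k(D, k_range)
    return select_cluster(result, D, props, inferred_type)
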