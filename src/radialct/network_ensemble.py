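"""3D force-directed models of the strong-contact network.

The thresholded strong-interaction matrix is treated as a weighted
adjacency matrix: nodes are genomic bins, edge weights the strong
contact values. A 3D Fruchterman-Reingold layout with a central gravity
term arranges the network in space; because the strong matrix is
dominated by intra-chromosomal contacts, bins of a chromosome coalesce
into a territory, while the sparser trans edges position territories
relative to one another. An ensemble of layouts from independent random
initializations models cell-to-cell variability in territory placement.

Per layout, a minimum-volume enclosing ellipsoid (Khachiyan's algorithm)
stands in for the nuclear envelope; its center is the nucleus center.
Each chromosome territory's radial position is the Euclidean distance of
its center of mass from the nucleus center, min-max normalized within
the layout so models with different overall extents are comparable. The
ensemble yields a distance matrix D of shape (n_models, 23).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._fr import _apply, _attraction, _repulsion
from .hic_io import BinTable
from .strong_contacts import StrongMatrix

__all__ = [
    "Layout3D",
    "EllipsoidFit",
    "DistanceMatrix",
    "build_graph",
    "fr_layout_3d",
    "generate_ensemble",
    "fit_mve",
    "chromosome_com",
    "radial_distances",
    "build_distance_matrix",
    "ensemble_distance_matrix",
]


@dataclass
class Layout3D:
    coords: np.ndarray     # (n_nodes, 3)
    nodes: np.ndarray      # bin indices, parallel to coords rows
    chrom: np.ndarray      # chromosome label per node
    seed: int


@dataclass
class EllipsoidFit:
    center: np.ndarray     # (3,)
    shape: np.ndarray      # (3, 3) SPD matrix A: (x-c)^T A (x-c) <= 1
    tolerance: float


@dataclass
class DistanceMatrix:
    values: np.ndarray     # (n_models, n_chrom), rows min-max in [0, 1]
    chrom_order: list[str]
    model_seeds: list[int]


def build_graph(S: StrongMatrix, bins: BinTable | None = None) -> nx.Graph:
    """Undirected weighted graph of strong contacts.

    Self-loops (diagonal entries) carry no layout information and are
    dropped. Bins with no strong off-diagonal contact are excluded.
    """
    bins = bins if bins is not None else S.bins
    iu, ju = np.triu_indices_from(S.values, k=1)
    w = S.values[iu, ju]
    nz = w > 0
    if not nz.any():
        raise ValueError("strong matrix has no off-diagonal contacts; empty graph")
    G = nx.Graph()
    chrom = bins.chrom
    for i, j, wij in zip(iu[nz], ju[nz], w[nz]):
        G.add_edge(int(i), int(j), weight=float(wij))
    nx.set_node_attributes(G, {n: chrom[n] for n in G.nodes}, "chrom")
    return G


def fr_layout_3d(
    G: nx.Graph,
    seed: int,
    iterations: int = 500,
    gravity: float = 1.0,
) -> Layout3D:
    """Weighted 3D Fruchterman-Reingold layout with central gravity.

    Classic FR forces — repulsion k^2/d between every node pair,
    attraction d^2/k along edges scaled by normalized edge weight — plus
    a spring-like gravity pulling every node toward the instantaneous
    centroid, which keeps disconnected components bounded. Initial
    coordinates are uniform in the unit cube from the seeded RNG;
    displacement per step is capped by a linearly cooling temperature.
    Deterministic for a given seed.
    """
    nodes = np.array(sorted(G.nodes), dtype=np.int64)
    index = {n: i for i, n in enumerate(nodes)}
    edges = np.array(
        [(index[u], index[v], d["weight"]) for u, v, d in G.edges(data=True)]
    )
    eu = edges[:, 0].astype(np.int64)
    ev = edges[:, 1].astype(np.int64)
    w = edges[:, 2].astype(np.float64)
    w = w / w.mean()  # weight scale-free: only relative strength matters
    n = len(nodes)
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, 3))

    k = (1.0 / n) ** (1.0 / 3.0)  # ideal pair distance for unit volume
    k2 = k * k
    t0 = 0.1
    for it in range(iterations):
        disp = _repulsion(X, k2)
        disp = _attraction(X, eu, ev, w, k, disp)
        centroid = X.mean(axis=0)
        disp += gravity * (centroid - X)
        t = t0 * (1.0 - it / iterations)
        X = _apply(X, disp, t)
    chrom = np.array([G.nodes[n]["chrom"] for n in nodes])
    return Layout3D(X, nodes, chrom, seed)


def generate_ensemble(
    G: nx.Graph, n_s: int, base_seed: int, iterations: int = 500,
    gravity: float = 1.0,
) -> list[Layout3D]:
    """n_s independent layouts seeded base_seed .. base_seed + n_s - 1."""
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    return [
        fr_layout_3d(G, base_seed + i, iterations=iterations, gravity=gravity)
        for i in range(n_s)
    ]


def fit_mve(points: np.ndarray, epsilon: float = 1e-3,
            max_iter: int = 10000) -> EllipsoidFit:
    """(1+epsilon)-approximate minimum-volume enclosing ellipsoid.

    Khachiyan's barycentric-coordinate ascent: maintain weights u over
    the points, repeatedly shift mass onto the point farthest outside
    the current trial ellipsoid until every point satisfies
    (x-c)^T A (x-c) <= 1 + epsilon. Degenerate (coplanar) point sets get
    a ridge-regularized fit with a warning.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points for an MVE in {d}-D")
    Q = np.vstack([P.T, np.ones(n)])
    u = np.full(n, 1.0 / n)
    err = np.inf
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        try:
            M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        except np.linalg.LinAlgError:
            M = np.einsum(
                "ij,ji->i", Q.T, np.linalg.solve(X + 1e-10 * np.eye(d + 1), Q)
            )
        j = int(np.argmax(M))
        maximum = M[j]
        err = maximum / (d + 1) - 1.0
        if err <= epsilon:
            break
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        u *= 1.0 - step
        u[j] += step
    center = P.T @ u
    cov = P.T @ (u[:, None] * P) - np.outer(center, center)
    try:
        A = np.linalg.inv(cov) / d
        if np.linalg.eigvalsh(A).min() <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("degenerate point set; regularizing MVE shape matrix")
        A = np.linalg.inv(cov + 1e-9 * np.trace(cov) / d * np.eye(d)) / d
    # guarantee enclosure: scale so the farthest point is on the surface
    centered = P - center
    s = float(np.einsum("ij,jk,ik->i", centered, A, centered).max())
    if s > 1.0:
        A = A / s
    return EllipsoidFit(center, A, epsilon)


def mve_volume(fit: EllipsoidFit) -> float:
    """Volume of the fitted ellipsoid (4/3 pi / sqrt(det A) in 3-D)."""
    d = fit.shape.shape[0]
    from scipy.special import gamma
    unit_ball = np.pi ** (d / 2) / gamma(d / 2 + 1)
    return float(unit_ball / np.sqrt(np.linalg.det(fit.shape)))


def chromosome_com(layout: Layout3D, chrom_order: list[str]) -> np.ndarray:
    """Unweighted center of mass of each chromosome territory."""
    coms = np.empty((len(chrom_order), 3))
    for i, c in enumerate(chrom_order):
        mask = layout.chrom == c
        if not mask.any():
            raise ValueError(f"chromosome {c} has no nodes in the layout")
        coms[i] = layout.coords[mask].mean(axis=0)
    return coms


def radial_distances(layout: Layout3D, fit: EllipsoidFit,
                     chrom_order: list[str]) -> np.ndarray:
    """Per-CT distance from nucleus center, min-max normalized to [0, 1]."""
    coms = chromosome_com(layout, chrom_order)
    dist = np.linalg.norm(coms - fit.center, axis=1)
    lo, hi = dist.min(), dist.max()
    if hi == lo:
        warnings.warn("all territories equidistant from center; distances set to 0.5")
        return np.full(len(chrom_order), 0.5)
    return (dist - lo) / (hi - lo)


def build_distance_matrix(
    ensemble: list[Layout3D],
    fits: list[EllipsoidFit],
    chrom_order: list[str],
) -> DistanceMatrix:
    if len(ensemble) != len(fits):
        raise ValueError("ensemble and fits must have equal length")
    rows, seeds = [], []
    for layout, fit in zip(ensemble, fits):
        try:
            rows.append(radial_distances(layout, fit, chrom_order))
            seeds.append(layout.seed)
        except ValueError as exc:
            warnings.warn(f"model seed {layout.seed} dropped: {exc}")
    return DistanceMatrix(np.array(rows), list(chrom_order), seeds)


def ensemble_distance_matrix(
    S: StrongMatrix,
    n_s: int,
    base_seed: int,
    iterations: int = 500,
    gravity: float = 1.0,
    epsilon: float = 1e-3,
    chrom_order: list[str] | None = None,
) -> DistanceMatrix:
    """Full ensemble stage: graph -> n_s layouts -> MVE fits -> D matrix."""
    G = build_graph(S)
    chrom_order = chrom_order or S.bins.chromosomes
    ensemble = generate_ensemble(G, n_s, base_seed, iterations, gravity)
    fits = [fit_mve(lay.coords, epsilon) for lay in ensemble]
    return build_distance_matrix(ensemble, fits, chrom_order)
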