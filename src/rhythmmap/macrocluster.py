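"""Macrocluster generation: KNN-constrained Ward clustering of latent nodes.

The methodological core of the pipeline: instead of clustering reference
vectors freely (which can glue together latent regions that are far apart on
the manifold) or with a fixed topological constraint, neighborhoods are
derived from the data itself. Each latent node becomes a point in R^3 —
its two latent coordinates plus the magnification factor at that node — and
a k-nearest-neighbor graph (k = 5, Euclidean distance, union-symmetrized)
over those points constrains which clusters of reference vectors may merge
during agglomerative (Ward) clustering. High-magnification ridges separate
neighborhoods, so macroclusters tend not to straddle sparse, stretched
regions of the manifold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from rhythmmap.gtm import LatentGrid
from rhythmmap.magnification import MagnificationField

__all__ = [
    "ConstraintGraph",
    "MacroclusterPartition",
    "build_knn_points",
    "knn_neighborhoods",
    "build_constraint_graph",
    "constrained_hclust",
    "map_to_latent",
]

SCALINGS = ("minmax", "none", "zscore")


@dataclass
class MacroclusterPartition:
    """Per-node macrocluster labels (1..M) plus provenance.

    ``linkage`` records each merge as (cluster_a, cluster_b, ward_distance,
    new_size, relaxed); ``relaxations`` lists merges that had to ignore the
    constraint graph because it had more components than requested clusters.
    ``diagnosis`` is filled in by the screening module.
    """

    labels: np.ndarray  # length K, values in 1..M
    M: int
    graph: nx.Graph
    linkage: list[tuple[int, int, float, int, bool]] = field(default_factory=list)
    relaxations: list[tuple[int, int]] = field(default_factory=list)
    diagnosis: dict[int, str] | None = None

    @property
    def K(self) -> int:
        return self.labels.size

    def members(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.labels == m)

    def is_connected(self) -> bool:
        """True when every macrocluster induces a connected subgraph."""
        for m in range(1, self.M + 1):
            sub = self.graph.subgraph(self.members(m).tolist())
            if sub.number_of_nodes() and not nx.is_connected(sub):
                return False
        return True

    def linkage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage,
            columns=["cluster_a", "cluster_b", "ward_distance", "new_size", "relaxed"],
        )


# kept as a thin alias so the constraint graph travels with its k
ConstraintGraph = nx.Graph


def build_knn_points(
    grid: LatentGrid, mf: MagnificationField, scaling: str = "minmax"
) -> np.ndarray:
    """Embed each latent node as (u1, u2, MF) with per-coordinate scaling.

    The magnification factor is unbounded while the latent coordinates live
    in [-1, 1]; the default min-max scaling puts all three on [0, 1] so
    neither dominates the Euclidean KNN.
    """
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}, got {scaling!r}")
    pts = np.column_stack([grid.nodes, mf.values])
    if scaling == "none":
        return pts
    out = pts.astype(float).copy()
    for j in range(3):
        col = out[:, j]
        rng = col.max() - col.min()
        if scaling == "minmax":
            if rng == 0:
                if j == 2:
                    warnings.warn(
                        "constant magnification field; MF coordinate set to 0.5",
                        stacklevel=2,
                    )
                out[:, j] = 0.5
            else:
                out[:, j] = (col - col.min()) / rng
        else:  # zscore
            sd = col.std()
            out[:, j] = 0.0 if sd == 0 else (col - col.mean()) / sd
    return out


def knn_neighborhoods(points: np.ndarray, k: int = 5) -> list[np.ndarray]:
    """The k nearest other points of each point, Euclidean distance.

    Distance ties are broken toward the lower point index (stable sort).
    """
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k must be < number of points ({n}), got {k}")
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    hoods = []
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        hoods.append(np.sort(order[:k]))
    return hoods


def build_constraint_graph(neighborhoods: list[np.ndarray]) -> nx.Graph:
    """Union-symmetrized KNN adjacency: edge (i, j) iff j in kNN(i) or i in kNN(j)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(neighborhoods)))
    for i, hood in enumerate(neighborhoods):
        for j in hood:
            if int(j) != i:
                g.add_edge(i, int(j))
    g.graph["n_components"] = nx.number_connected_components(g)
    return g


def _ward_distance(size_a, cent_a, size_b, cent_b) -> float:
    """Ward linkage distance (scipy convention: the square root form)."""
    d2 = float(np.sum((cent_a - cent_b) ** 2))
    return np.sqrt(2.0 * size_a * size_b / (size_a + size_b) * d2)


def constrained_hclust(
    Y: np.ndarray, graph: nx.Graph, M: int = 5
) -> MacroclusterPartition:
    """Agglomerative Ward clustering of reference vectors under graph constraints.

    Only cluster pairs joined by at least one constraint-graph edge may
    merge; at each step the connected pair with minimal Ward distance is
    merged. When the graph has more components than M, the remaining merges
    join the two clusters with minimal Ward distance regardless of edges
    (each such relaxation is recorded). Final labels are renumbered 1..M by
    smallest member node index.
    """
    Y = np.asarray(Y, dtype=float)
    K = Y.shape[0]
    if M > K:
        raise ValueError(f"M = {M} exceeds the number of nodes K = {K}")
    if M < 1:
        raise ValueError("M must be >= 1")

    members: dict[int, list[int]] = {i: [i] for i in range(K)}
    cents: dict[int, np.ndarray] = {i: Y[i].copy() for i in range(K)}
    # adjacency between live clusters (cluster ids = smallest member index
    # is NOT maintained during merging; ids are arbitrary dict keys)
    adj: dict[int, set[int]] = {i: set(graph.neighbors(i)) for i in range(K)}
    linkage: list[tuple[int, int, float, int, bool]] = []
    relaxations: list[tuple[int, int]] = []

    while len(members) > M:
        best = None
        best_d = np.inf
        ids = sorted(members)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                if b not in adj[a]:
                    continue
                d = _ward_distance(len(members[a]), cents[a], len(members[b]), cents[b])
                if d < best_d:
                    best_d, best = d, (a, b)
        relaxed = best is None
        if relaxed:
            # constraint graph exhausted (more components than M): join the
            # closest pair outright and log the relaxation
            for ai, a in enumerate(ids):
                for b in ids[ai + 1 :]:
                    d = _ward_distance(len(members[a]), cents[a], len(members[b]), cents[b])
                    if d < best_d:
                        best_d, best = d, (a, b)
            relaxations.append(best)
            warnings.warn(
                f"constraint graph has more components than M={M}; "
                f"relaxed merge of clusters {best}",
                stacklevel=2,
            )
        a, b = best
        na, nb = len(members[a]), len(members[b])
        cents[a] = (na * cents[a] + nb * cents[b]) / (na + nb)
        members[a].extend(members[b])
        adj[a] |= adj[b]
        adj[a].discard(a)
        adj[a].discard(b)
        for c in adj.pop(b):
            if c in adj and c != a:
                adj[c].discard(b)
                adj[c].add(a)
        del members[b], cents[b]
        linkage.append((a, b, best_d, na + nb, relaxed))

    order = sorted(members, key=lambda c: min(members[c]))
    labels = np.empty(K, dtype=int)
    for new_label, c in enumerate(order, start=1):
        labels[members[c]] = new_label
    return MacroclusterPartition(
        labels=labels, M=len(order), graph=graph, linkage=linkage, relaxations=relaxations
    )


def map_to_latent(partition: MacroclusterPartition, grid: LatentGrid) -> pd.DataFrame:
    """Per-node (node_row, node_col, macrocluster) table for plotting."""
    if partition.K != grid.K:
        raise ValueError("partition size does not match the grid")
    cols = grid.shape[1]
    idx = np.arange(grid.K)
    return pd.DataFrame(
        {
            "node_row": idx // cols,
            "node_col": idx % cols,
            "macrocluster": partition.labels,
        }
    )


def macrocluster_pipeline(
    results,
    k: int = 5,
    M: int = 5,
    scaling: str = "minmax",
) -> MacroclusterPartition:
    """Convenience: magnification -> KNN constraint graph -> constrained Ward."""
    mf = results.magnification_ if results.magnification_ is not None else results.attach_magnification()
    pts = build_knn_points(results.model.grid, mf, scaling=scaling)
    hoods = knn_neighborhoods(pts, k=k)
    graph = build_constraint_graph(hoods)
    return constrained_hclust(results.reference_vectors_, graph, M=M)
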