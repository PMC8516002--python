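"""kNN graph construction, Louvain community detection, and 2-D embedding."""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class NeighborGraph:
    graph: ig.Graph          # weighted, undirected, no self-loops
    metric: str
    k: int

    @property
    def n_components(self) -> int:
        return len(self.graph.connected_components())


@dataclass
class ClusterAssignment:
    labels: np.ndarray       # per-cell labels, contiguous from 1
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def knn_graph(coords: np.ndarray, k: int = 50, metric: str = "cosine",
              mutual: bool = True) -> NeighborGraph:
    """Symmetrized kNN graph weighted by similarity.

    Edges connect points that are k-nearest neighbors of each other
    (default) or of at least one endpoint (``mutual=False``).  Cosine weights
    are 1 - distance clipped to (0, 1]; euclidean weights 1/(1 + distance).
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    if metric not in ("cosine", "euclidean"):
        raise ValueError(f"unsupported metric: {metric}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(coords)
    dist, nbr = nn.kneighbors(coords)
    pairs: dict[tuple[int, int], float] = {}
    seen = [set(row[1:]) for row in nbr]
    for i in range(n):
        for j_pos in range(1, k + 1):
            j = int(nbr[i, j_pos])
            if i == j:
                continue
            if mutual and i not in seen[j]:
                continue
            key = (min(i, j), max(i, j))
            d = float(dist[i, j_pos])
            if metric == "cosine":
                w = min(max(1.0 - d, 1e-12), 1.0)
            else:
                w = 1.0 / (1.0 + d)
            pairs[key] = max(pairs.get(key, 0.0), w)
    g = ig.Graph(n=n, edges=list(pairs), edge_attrs={"weight": list(pairs.values())})
    return NeighborGraph(graph=g, metric=metric, k=k)


def louvain_cluster(g: NeighborGraph, seed: int = 0) -> ClusterAssignment:
    """Modularity-optimizing Louvain partition, deterministic given seed."""
    if g.graph.vcount() == 0:
        raise ValueError("empty graph")
    state = random.Random(seed)
    ig.set_random_number_generator(state)
    try:
        part = g.graph.community_multilevel(
            weights="weight" if g.graph.ecount() else None
        )
    finally:
        ig.set_random_number_generator(random)
    labels = np.asarray(part.membership, dtype=np.int64) + 1
    mod = g.graph.modularity(
        part.membership, weights="weight" if g.graph.ecount() else None
    )
    return ClusterAssignment(labels=labels, modularity=float(mod))


def embed_2d(coords: np.ndarray, n_neighbors: int = 50, min_dist: float = 0.1,
             metric: str = "cosine", seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding, deterministic given seed."""
    import umap  # deferred: heavy import

    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape[0] < 10:
        raise ValueError("need at least 10 cells to embed")
    reducer = umap.UMAP(
        n_components=2, n_neighbors=min(n_neighbors, coords.shape[0] - 1),
        min_dist=min_dist, metric=metric, random_state=seed,
    )
    return np.asarray(reducer.fit_transform(coords), dtype=np.float64)
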