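"""Principal-tree trajectories, pseudotime, and branch analysis.

The principal graph is a refined-landmark minimum spanning tree: k-means
landmarks are iteratively shifted to the mean of their assigned cells, a
Euclidean MST is built over the surviving landmarks, and every cell is
projected onto its nearest tree edge.  Pseudotime is the geodesic distance
along the tree from a developmental root — chosen as the node whose cells
carry the earliest stage annotation — to each cell's projection point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from ._stats import specificity_score
from .io import CountMatrix


@dataclass
class PrincipalGraph:
    node_coords: np.ndarray                 # n_nodes x d
    edges: list[tuple[int, int]]            # tree edges (u < v)
    edge_lengths: np.ndarray
    cell_edge: np.ndarray                   # per-cell edge index (-1: none)
    cell_offset: np.ndarray                 # distance from edge endpoint u
    cell_point: np.ndarray                  # projected coordinates
    root_node: int | None = None
    pseudotime: np.ndarray | None = None
    node_distances: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def branch_nodes(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.degrees() >= 3)]

    def nearest_node_per_cell(self) -> np.ndarray:
        """Node each cell's projection sits closest to (by along-edge offset)."""
        out = np.full(self.cell_edge.shape[0], -1, dtype=int)
        for c, e in enumerate(self.cell_edge):
            if e < 0:
                out[c] = 0 if self.n_nodes else -1
                continue
            u, v = self.edges[e]
            out[c] = u if self.cell_offset[c] <= self.edge_lengths[e] / 2 else v
        return out


def _project_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto segment ab; returns (offset from a, distance)."""
    ab = b - a
    L2 = float(ab @ ab)
    if L2 == 0:
        t = np.zeros(points.shape[0])
    else:
        t = np.clip(((points - a) @ ab) / L2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(points - proj, axis=1)
    return t * np.sqrt(L2), d


def learn_principal_graph(coords: np.ndarray, n_landmarks: int = 30,
                          seed: int = 0, max_iter: int = 50,
                          tol: float = 1e-4) -> PrincipalGraph:
    """Fit a principal tree through the cell cloud (no root yet)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n_landmarks < 1:
        raise ValueError("n_landmarks must be >= 1")
    n_landmarks = min(n_landmarks, n)
    scale = float(np.linalg.norm(coords.std(axis=0)))
    if scale == 0 or n == 1:  # all cells identical: single-node graph
        node = coords.mean(axis=0, keepdims=True)
        return PrincipalGraph(
            node_coords=node, edges=[], edge_lengths=np.zeros(0),
            cell_edge=np.full(n, -1), cell_offset=np.zeros(n),
            cell_point=np.tile(node, (n, 1)),
        )

    if n_landmarks == 1:
        centers = coords.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=n_landmarks, n_init=10, random_state=seed)
        km.fit(coords)
        centers = km.cluster_centers_.copy()

    # SimplePPT-style refinement: shift each landmark to the mean of its cells
    for _ in range(max_iter):
        assign = np.argmin(cdist(coords, centers), axis=1)
        new = centers.copy()
        for j in range(centers.shape[0]):
            members = coords[assign == j]
            if len(members):
                new[j] = members.mean(axis=0)
        move = float(np.max(np.linalg.norm(new - centers, axis=1)))
        centers = new
        if move < tol * scale:
            break
    assign = np.argmin(cdist(coords, centers), axis=1)
    occupied = np.flatnonzero(np.bincount(assign, minlength=centers.shape[0]) > 0)
    centers = centers[occupied]
    k = centers.shape[0]

    if k == 1:
        proj = np.tile(centers, (n, 1))
        return PrincipalGraph(
            node_coords=centers, edges=[], edge_lengths=np.zeros(0),
            cell_edge=np.full(n, -1), cell_offset=np.zeros(n), cell_point=proj,
        )

    dmat = cdist(centers, centers)
    mst = minimum_spanning_tree(dmat).tocoo()
    edges = [(min(int(u), int(v)), max(int(u), int(v)))
             for u, v in zip(mst.row, mst.col)]
    edges.sort()
    lengths = np.array([np.linalg.norm(centers[u] - centers[v])
                        for u, v in edges])

    cell_edge = np.zeros(n, dtype=int)
    cell_offset = np.zeros(n)
    cell_point = np.zeros_like(coords)
    best_d = np.full(n, np.inf)
    for e, (u, v) in enumerate(edges):
        off, d = _project_to_segment(coords, centers[u], centers[v])
        better = d < best_d
        best_d[better] = d[better]
        cell_edge[better] = e
        cell_offset[better] = off[better]
    for c in range(n):
        u, v = edges[cell_edge[c]]
        a, b = centers[u], centers[v]
        L = lengths[cell_edge[c]]
        t = cell_offset[c] / L if L > 0 else 0.0
        cell_point[c] = a + t * (b - a)

    return PrincipalGraph(
        node_coords=centers, edges=edges, edge_lengths=lengths,
        cell_edge=cell_edge, cell_offset=cell_offset, cell_point=cell_point,
    )


def _tree_distances(g: PrincipalGraph) -> np.ndarray:
    k = g.n_nodes
    rows = [u for u, _ in g.edges] + [v for _, v in g.edges]
    cols = [v for _, v in g.edges] + [u for u, _ in g.edges]
    w = np.concatenate([g.edge_lengths, g.edge_lengths]) if g.edges else np.zeros(0)
    adj = sp.csr_matrix((w, (rows, cols)), shape=(k, k))
    return shortest_path(adj, directed=False)


def assign_pseudotime(g: PrincipalGraph,
                      stage_annotation: np.ndarray | None = None,
                      root: int | None = None) -> PrincipalGraph:
    """Pick the root and measure geodesic pseudotime to every cell.

    The root is the tree node whose projected cells have the smallest mean
    annotated stage (ties: the node with more annotated cells, then the lower
    node id); an explicit ``root`` overrides the annotation.
    """
    n_cells = g.cell_edge.shape[0]
    if g.n_nodes == 1 or not g.edges:
        g.root_node = 0 if root is None else root
        g.pseudotime = np.zeros(n_cells)
        return g

    if root is None:
        if stage_annotation is None:
            raise ValueError("no stage annotation: supply an explicit root")
        stages = np.asarray(stage_annotation, dtype=np.float64)
        if not np.isfinite(stages).any():
            raise ValueError("no annotated cells: supply an explicit root")
        nearest = g.nearest_node_per_cell()
        best = None
        for node in range(g.n_nodes):
            vals = stages[(nearest == node) & np.isfinite(stages)]
            if len(vals) == 0:
                continue
            key = (vals.mean(), -len(vals), node)
            if best is None or key < best:
                best = key
        root = best[2]

    dist = _tree_distances(g)
    pt = np.zeros(n_cells)
    for c in range(n_cells):
        e = g.cell_edge[c]
        if e < 0:
            pt[c] = 0.0
            continue
        u, v = g.edges[e]
        off, L = g.cell_offset[c], g.edge_lengths[e]
        pt[c] = min(dist[root, u] + off, dist[root, v] + (L - off))
    g.root_node = int(root)
    g.pseudotime = pt
    g.node_distances = dist
    return g


def scrolling_stage_profile(pseudotime: np.ndarray, stages: np.ndarray,
                            window: int = 20) -> pd.DataFrame:
    """Sliding-window (step 1) mean developmental stage along pseudotime."""
    pseudotime = np.asarray(pseudotime, dtype=np.float64)
    stages = np.asarray(stages, dtype=np.float64)
    n = len(pseudotime)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window={window} exceeds {n} cells")
    order = np.argsort(pseudotime, kind="stable")
    pt, st = pseudotime[order], stages[order]
    kernel = np.ones(window) / window
    mean_stage = np.convolve(st, kernel, mode="valid")
    mean_pt = np.convolve(pt, kernel, mode="valid")
    return pd.DataFrame({"pseudotime": mean_pt, "mean_stage": mean_stage})


def side_branch_cells(g: PrincipalGraph) -> tuple[np.ndarray, np.ndarray]:
    """Split cells at the (unique) branch point into side branch vs. main.

    The side branch is the subtree hanging off the degree>=3 node that holds
    the fewest projected cells.  Returns (branch cell idx, main cell idx).
    """
    bnodes = g.branch_nodes()
    if len(bnodes) != 1:
        raise ValueError(f"expected exactly one branch node, found {len(bnodes)}")
    b = bnodes[0]
    # connected components after removing the branch node
    adj: dict[int, list[int]] = {i: [] for i in range(g.n_nodes)}
    for u, v in g.edges:
        adj[u].append(v)
        adj[v].append(u)
    comp = np.full(g.n_nodes, -1)
    cid = 0
    for start in adj[b]:
        if comp[start] >= 0:
            continue
        stack = [start]
        while stack:
            x = stack.pop()
            if comp[x] >= 0 or x == b:
                continue
            comp[x] = cid
            stack.extend(y for y in adj[x] if y != b and comp[y] < 0)
        cid += 1
    nearest = g.nearest_node_per_cell()
    cell_comp = np.where(nearest == b, -1, comp[nearest])
    sizes = np.bincount(cell_comp[cell_comp >= 0], minlength=cid)
    side = int(np.argmin(sizes))
    branch_idx = np.flatnonzero(cell_comp == side)
    main_idx = np.flatnonzero(cell_comp != side)
    return branch_idx, main_idx


def branch_specific_genes(m: CountMatrix, branch_cells: np.ndarray,
                          main_cells: np.ndarray,
                          size_factors: np.ndarray | None = None,
                          spec_min: float = 0.8, frac_min: float = 0.1,
                          mean_min: float = 0.25) -> pd.DataFrame:
    """Genes whose expression is specific to the side branch or the main path.

    A gene passes when its Jensen-Shannon specificity between the two cell
    sets exceeds ``spec_min``, it is detected in at least ``frac_min`` of the
    cells considered, and its mean normalized expression exceeds ``mean_min``.
    """
    branch_cells = np.asarray(branch_cells)
    main_cells = np.asarray(main_cells)
    if len(branch_cells) == 0 or len(main_cells) == 0:
        raise ValueError("both cell sets must be nonempty")
    expr = m.dense()
    if size_factors is not None:
        safe = np.where(np.isnan(size_factors) | (size_factors == 0),
                        1.0, size_factors)
        expr = expr / safe[None, :]
    considered = np.concatenate([branch_cells, main_cells])
    sub = expr[:, considered]
    frac = (sub > 0).mean(axis=1)
    mean_all = sub.mean(axis=1)
    mean_branch = expr[:, branch_cells].mean(axis=1)
    mean_main = expr[:, main_cells].mean(axis=1)
    specs = np.zeros(m.n_genes)
    which = np.empty(m.n_genes, dtype=object)
    for i in range(m.n_genes):
        s, arg = specificity_score(np.array([mean_branch[i], mean_main[i]]))
        specs[i] = s
        which[i] = "branch" if arg == 0 else "main"
    table = pd.DataFrame({
        "gene": m.gene_ids, "mean_branch": mean_branch, "mean_main": mean_main,
        "frac_expressing": frac, "mean_expr": mean_all,
        "specificity": specs, "specific_to": which,
    })
    table["passes"] = (
        (table.specificity > spec_min)
        & (table.frac_expressing >= frac_min)
        & (table.mean_expr > mean_min)
    )
    return table
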