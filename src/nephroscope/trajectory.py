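"""Principal-tree pseudotime.

A deliberately simple principal-tree learner: seeded k-means centroids in
the embedding space are joined by a Euclidean minimum spanning tree, and
every cell is projected to the nearest point on any tree edge.  Rooting the
tree at a node (or at the node nearest a named cluster's centroid, e.g. the
pretubular aggregate when ordering nephron differentiation) defines
pseudotime as geodesic arc length along the tree from the root to the
cell's projection.  Branch ids are the maximal tree segments between
branch points (nodes of degree >= 3) and leaves.

This is a transparent stand-in for reversed-graph-embedding methods
(DDRTree/Monocle 2): same contract — tree, root, geodesic pseudotime,
branch assignment — with a fraction of the machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .clustering import ClusterAssignment
from .io import EmbeddingMatrix


class ParameterError(ValueError):
    pass


@dataclass
class PrincipalTree:
    cells: list[str]
    nodes: np.ndarray                  # (n_nodes, dim) coordinates
    edges: list[tuple[int, int]]
    cell_edge: np.ndarray              # per-cell edge index
    cell_offset: np.ndarray            # per-cell arc position within edge [0, len]
    cell_projection: np.ndarray        # (n_cells, dim) projected coordinates

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.nodes.shape[0]))
        for u, v in self.edges:
            g.add_edge(u, v, weight=float(np.linalg.norm(self.nodes[u] - self.nodes[v])))
        return g

    def branch_points(self) -> list[int]:
        g = self.graph()
        return [n for n in g.nodes if g.degree[n] >= 3]


@dataclass
class PseudotimeResult:
    cells: list[str]
    pseudotime: np.ndarray
    branch: np.ndarray     # per-cell branch id (int)
    root_node: int
    branch_nodes: list[int]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"pseudotime": self.pseudotime, "branch": self.branch},
                            index=pd.Index(self.cells, name="cell"))


def _mst_edges(nodes: np.ndarray) -> list[tuple[int, int]]:
    mst = minimum_spanning_tree(cdist(nodes, nodes)).toarray()
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(mst))]


def _prune_spurs(nodes: np.ndarray, edges: list[tuple[int, int]],
                 min_arm_nodes: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Iteratively drop leaf arms with fewer than ``min_arm_nodes`` nodes.

    Such spurs are junction artifacts of the centroid MST: a single stray
    node hanging off a branch point.  Arms attached to the tree root of a
    path (no branch point) are never pruned.
    """
    while True:
        g = nx.Graph(edges)
        g.add_nodes_from(range(nodes.shape[0]))
        bps = [n for n in g.nodes if g.degree[n] >= 3]
        if not bps:
            return nodes, edges
        drop: list[int] = []
        for leaf in [n for n in g.nodes if g.degree[n] == 1]:
            arm = [leaf]
            cur, prev = leaf, None
            while g.degree[cur] < 3:
                nxt = [w for w in g.neighbors(cur) if w != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                if g.degree[cur] < 3:
                    arm.append(cur)
            if g.degree[cur] >= 3 and len(arm) < min_arm_nodes:
                drop = arm
                break
        if not drop:
            return nodes, edges
        keep = np.setdiff1d(np.arange(nodes.shape[0]), drop)
        nodes = nodes[keep]
        edges = _mst_edges(nodes)


def learn_tree(embedding: EmbeddingMatrix, n_nodes: int | None = None, seed: int = 0,
               min_arm_nodes: int = 2) -> PrincipalTree:
    """Fit the centroid-MST principal tree and project every cell onto it.

    Seeded k-means places ``n_nodes`` centroids, the Euclidean MST joins
    them, and leaf arms shorter than ``min_arm_nodes`` nodes (single-node
    junction spurs) are pruned before cells are projected onto the edges.
    """
    x = embedding.coordinates
    n_cells = x.shape[0]
    if n_nodes is None:
        n_nodes = max(10, int(np.ceil(n_cells / 100)))
    if n_nodes < 2:
        raise ParameterError("n_nodes must be >= 2")
    if n_nodes > n_cells:
        raise ParameterError("more tree nodes than cells")
    km = KMeans(n_clusters=n_nodes, random_state=seed, n_init=10).fit(x)
    nodes = km.cluster_centers_
    edges = _mst_edges(nodes)
    nodes, edges = _prune_spurs(nodes, edges, min_arm_nodes)

    # project each cell to the nearest point on any edge segment
    best_d = np.full(n_cells, np.inf)
    cell_edge = np.zeros(n_cells, dtype=int)
    cell_off = np.zeros(n_cells)
    proj = np.zeros_like(x)
    for ei, (u, v) in enumerate(edges):
        a, b = nodes[u], nodes[v]
        ab = b - a
        L2 = float(ab @ ab)
        t = np.clip(((x - a) @ ab) / max(L2, 1e-30), 0.0, 1.0)
        p = a[None, :] + t[:, None] * ab[None, :]
        dd = np.linalg.norm(x - p, axis=1)
        upd = dd < best_d
        best_d[upd] = dd[upd]
        cell_edge[upd] = ei
        cell_off[upd] = t[upd] * np.sqrt(L2)
        proj[upd] = p[upd]
    tree = PrincipalTree(list(embedding.cells), nodes, edges, cell_edge, cell_off, proj)
    g = tree.graph()
    if not nx.is_tree(g):
        raise RuntimeError("internal error: MST is not a tree")
    return tree


def resolve_root(tree: PrincipalTree, embedding: EmbeddingMatrix,
                 assign: ClusterAssignment, root_cluster) -> int:
    """Tree node nearest to the named cluster's centroid."""
    if list(assign.cells) != list(embedding.cells):
        raise ParameterError("assignment does not match the embedding cells")
    m = assign.labels == root_cluster
    if not np.any(m):
        raise ParameterError(f"no cells labeled {root_cluster!r}")
    centroid = embedding.coordinates[m].mean(axis=0)
    return int(np.linalg.norm(tree.nodes - centroid, axis=1).argmin())


def compute_pseudotime(tree: PrincipalTree, root: int) -> PseudotimeResult:
    """Geodesic arc-length pseudotime from the root along the tree.

    A cell projected at offset *o* on edge (u, v) has pseudotime
    ``min(d(root, u) + o, d(root, v) + (L - o))`` where *d* is the geodesic
    node distance and *L* the edge length.  Branch ids index the maximal
    segments of the tree between branch points and leaves.
    """
    g = tree.graph()
    if root not in g:
        raise ParameterError(f"root node {root} not in tree")
    if not nx.is_connected(g):
        raise RuntimeError("internal error: disconnected tree")
    dist = nx.single_source_dijkstra_path_length(g, root)

    # maximal segments: split the tree at branch points
    branch_nodes = set(tree.branch_points())
    seg_of_edge: dict[frozenset, int] = {}
    seg_id = 0
    visited: set[frozenset] = set()
    for u, v in tree.edges:
        e = frozenset((u, v))
        if e in visited:
            continue
        # walk the segment containing this edge
        seg_edges = [e]
        visited.add(e)
        for start in (u, v):
            prev_e = e
            node = start
            while node not in branch_nodes and g.degree[node] == 2:
                nbrs = [frozenset((node, w)) for w in g.neighbors(node)]
                nxt = [f for f in nbrs if f != prev_e and f not in visited]
                if not nxt:
                    break
                f = nxt[0]
                visited.add(f)
                seg_edges.append(f)
                (node,) = set(f) - {node}
                prev_e = f
        for f in seg_edges:
            seg_of_edge[f] = seg_id
        seg_id += 1

    n_cells = len(tree.cells)
    pt = np.zeros(n_cells)
    br = np.zeros(n_cells, dtype=int)
    lengths = {i: float(np.linalg.norm(tree.nodes[u] - tree.nodes[v]))
               for i, (u, v) in enumerate(tree.edges)}
    for i in range(n_cells):
        ei = int(tree.cell_edge[i])
        u, v = tree.edges[ei]
        o = float(tree.cell_offset[i])
        L = lengths[ei]
        pt[i] = min(dist[u] + o, dist[v] + (L - o))
        br[i] = seg_of_edge[frozenset((u, v))]
    return PseudotimeResult(list(tree.cells), pt, br, root, sorted(branch_nodes))


def pseudotime_by_cluster(res: PseudotimeResult, assign: ClusterAssignment) -> pd.DataFrame:
    """Quartile summaries of pseudotime per cluster, ordered by median."""
    if list(assign.cells) != list(res.cells):
        raise ParameterError("assignment does not match the pseudotime cells")
    df = pd.DataFrame({"pseudotime": res.pseudotime, "cluster": assign.labels})
    rows = []
    for lab, sub in df.groupby("cluster", sort=False):
        q = np.percentile(sub["pseudotime"], [25, 50, 75])
        rows.append({"cluster": lab, "n": len(sub), "q25": q[0], "median": q[1], "q75": q[2]})
    out = pd.DataFrame(rows).sort_values("median").reset_index(drop=True)
    return out
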