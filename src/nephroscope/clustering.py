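"""Hierarchical clustering of cells and literature-marker-guided merging.

Cells are clustered by Ward linkage on the correlation distance
``d(i, j) = 1 - Pearson r(i, j)`` computed over the highly variable genes.
The dendrogram is cut either at a height or to a requested number of
clusters, labels are renumbered by cluster size, and over-split clusters
can be merged — either by an explicit, audit-friendly merge map, or by an
automatic rule that iteratively merges sibling clusters whose mean
literature-marker profiles are nearly collinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix


class ParameterError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    """Per-cell labels plus the dendrogram and merge history."""

    cells: list[str]
    labels: np.ndarray                      # per-cell final labels (int or str)
    linkage: np.ndarray | None = None       # scipy linkage matrix
    merge_map: dict = field(default_factory=dict)  # original -> final label
    merge_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (len(self.cells),):
            raise ParameterError("labels must be one per cell")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()))

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    def relabeled(self, mapping: dict) -> "ClusterAssignment":
        new = np.array([mapping.get(l, l) for l in self.labels.tolist()], dtype=object)
        merge_map = {k: mapping.get(v, v) for k, v in self.merge_map.items()} if self.merge_map \
            else {l: mapping.get(l, l) for l in set(self.labels.tolist())}
        return ClusterAssignment(list(self.cells), new, self.linkage, merge_map,
                                 list(self.merge_history) + [dict(mapping)])


@dataclass
class ClusterProfile:
    """Cluster x gene mean-expression matrix and its gene-wise Z variant."""

    clusters: list
    genes: list[str]
    means: np.ndarray          # (n_clusters, n_genes)
    zscores: np.ndarray        # gene-wise standardized across clusters
    constant_genes: np.ndarray  # mask of genes with zero sd across clusters


def correlation_distance(x: ExpressionMatrix, genes: list[str] | None = None) -> np.ndarray:
    """Cell-cell distance ``1 - Pearson r`` over a gene subset."""
    vals = x.values if genes is None else x.values[x.gene_index(genes)]
    if vals.shape[0] < 2:
        raise ParameterError("need at least 2 genes for a correlation distance")
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = x.cells[int(np.argmax(sd == 0))]
        raise ParameterError(f"cell {bad!r} has zero variance over the selected genes")
    r = np.corrcoef(vals.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2, 0.0, 2.0)


def ward_cluster(d: np.ndarray) -> np.ndarray:
    """Ward-linkage merge tree (scipy linkage matrix) from a distance matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ParameterError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(d, checks=False), method="ward")


def cut_dendrogram(
    linkage: np.ndarray,
    cells: list[str],
    height: float | None = None,
    n_clusters: int | None = None,
) -> ClusterAssignment:
    """Cut the merge tree at a height or to a cluster count.

    Exactly one of ``height`` / ``n_clusters`` must be given.  Labels are
    renumbered 0, 1, ... by decreasing cluster size (ties by first
    occurrence).
    """
    if (height is None) == (n_clusters is None):
        raise ParameterError("give exactly one of height or n_clusters")
    if height is not None:
        raw = hierarchy.fcluster(linkage, t=height, criterion="distance")
    else:
        raw = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    labels = _relabel_by_size(raw)
    return ClusterAssignment(list(cells), labels, linkage)


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in raw])


def cluster_profile(
    x: ExpressionMatrix,
    assign: ClusterAssignment,
    genes: list[str] | None = None,
    ddof: int = 1,
) -> ClusterProfile:
    """Per-cluster mean expression, Z-standardized gene-wise across clusters.

    Zero-sd genes (including the single-cluster case) get an all-zero Z row
    and are flagged in ``constant_genes``.
    """
    if list(assign.cells) != list(x.cells):
        raise ParameterError("assignment does not match the matrix cells")
    gi = np.arange(x.n_genes) if genes is None else x.gene_index(genes)
    gene_names = [x.genes[i] for i in gi]
    uniq = sorted(set(assign.labels.tolist()), key=str)
    means = np.zeros((len(uniq), len(gi)))
    for i, lab in enumerate(uniq):
        m = assign.labels == lab
        if not np.any(m):
            raise ParameterError(f"empty cluster {lab!r}")
        means[i] = x.values[np.ix_(gi, np.flatnonzero(m))].mean(axis=1)
    if len(uniq) > 1:
        sd = means.std(axis=0, ddof=min(ddof, len(uniq) - 1))
    else:
        sd = np.zeros(len(gi))
    constant = sd == 0
    safe = np.where(constant, 1.0, sd)
    z = (means - means.mean(axis=0, keepdims=True)) / safe[None, :]
    z[:, constant] = 0.0
    return ClusterProfile(uniq, gene_names, means, z, constant)


def _cluster_tree_siblings(linkage: np.ndarray, labels: np.ndarray,
                           cells_order: np.ndarray | None = None) -> set[frozenset]:
    """Pairs of current clusters that are joined directly by some dendrogram
    node whose subtrees each contain exactly one cluster."""
    n = linkage.shape[0] + 1
    members: dict[int, set] = {i: {labels[i]} for i in range(n)}
    sibs: set[frozenset] = set()
    for i, (a, b, _, _) in enumerate(linkage):
        sa, sb = members[int(a)], members[int(b)]
        if len(sa) == 1 and len(sb) == 1 and sa != sb:
            sibs.add(frozenset(sa | sb))
        members[n + i] = sa | sb
    return sibs


def merge_clusters(
    assign: ClusterAssignment,
    profiles: ClusterProfile | None = None,
    merge_map: dict | None = None,
    auto_threshold: float | None = None,
) -> ClusterAssignment:
    """Merge clusters either by an explicit map or by profile similarity.

    Explicit mode applies ``merge_map`` (original label -> merged label)
    verbatim.  Auto mode iteratively merges, highest correlation first,
    pairs of dendrogram-sibling clusters whose literature-marker mean
    profiles have Pearson r > ``auto_threshold``; after each merge the
    merged profile is the size-weighted mean of its parts.
    """
    if (merge_map is None) == (auto_threshold is None):
        raise ParameterError("give exactly one of merge_map or auto_threshold")
    if merge_map is not None:
        known = set(assign.labels.tolist())
        unknown = set(merge_map) - known
        if unknown:
            raise ParameterError(f"merge_map references unknown labels: {sorted(map(str, unknown))}")
        return assign.relabeled(merge_map)

    if profiles is None:
        raise ParameterError("auto merging needs cluster profiles")
    labels = assign.labels.copy()
    sizes = {l: int((labels == l).sum()) for l in set(labels.tolist())}
    prof = {l: profiles.means[i].astype(float) for i, l in enumerate(profiles.clusters)}
    if set(prof) != set(sizes):
        raise ParameterError("profiles do not cover the assignment's clusters")
    history = []
    mapping = {l: l for l in sizes}
    while True:
        if assign.linkage is not None:
            current = np.array([mapping[l] for l in assign.labels.tolist()])
            sibs = _cluster_tree_siblings(assign.linkage, current)
            pairs = [tuple(sorted(p, key=str)) for p in sibs]
        else:
            keys = sorted(sizes, key=str)
            pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]
        best, best_r = None, auto_threshold
        for a, b in pairs:
            pa, pb = prof[a], prof[b]
            if pa.std() == 0 or pb.std() == 0:
                continue
            r = float(np.corrcoef(pa, pb)[0, 1])
            if r > best_r:
                best, best_r = (a, b), r
        if best is None:
            break
        a, b = best
        keep, drop = (a, b) if sizes[a] >= sizes[b] else (b, a)
        prof[keep] = (prof[keep] * sizes[keep] + prof[drop] * sizes[drop]) / (sizes[keep] + sizes[drop])
        sizes[keep] += sizes.pop(drop)
        del prof[drop]
        for k, v in mapping.items():
            if v == drop:
                mapping[k] = keep
        history.append({"merged": (a, b), "into": keep, "r": best_r})
    labels = np.array([mapping[l] for l in assign.labels.tolist()])
    out = ClusterAssignment(list(assign.cells), labels, assign.linkage,
                            dict(mapping), list(assign.merge_history) + history)
    return out
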