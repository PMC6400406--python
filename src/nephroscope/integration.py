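"""Cross-sample integration and differential expression.

**Batch correction** uses a mutual-nearest-neighbors (MNN) scheme in a
common principal-component space: for each query batch against the growing
reference, cell pairs that lie in each other's k-neighborhoods across
batches are taken to be the same biological state; each query cell is
shifted by a Gaussian-kernel-weighted average of its batch's pair
difference vectors.  The reference batch is never moved.

**Label transfer** assigns each unlabeled cell the majority cell type among
its 20 nearest labeled neighbors in corrected PC space (ties broken by the
smallest mean distance among tied classes).

**Differential expression** fits, per gene, a negative-binomial GLM (log
link) with the group contrast and a centered cellular detection-rate
covariate, with library-size offsets; gene-wise dispersions are estimated
by a within-group method of moments and shrunk toward an a + b/mu trend.
Group effects are tested by a likelihood-ratio test and adjusted with
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, EmbeddingMatrix
from .preprocess import library_size_factors, _robust_trend_fit


class ParameterError(ValueError):
    pass


@dataclass
class CorrectedSpace:
    cells: list[str]
    coordinates: np.ndarray    # (n_cells, n_pcs)
    batch: np.ndarray          # per-cell batch label
    mnn_pairs: list[tuple[int, int]]  # (reference index, query index) into `cells`

    def embedding(self) -> EmbeddingMatrix:
        return EmbeddingMatrix(self.cells, self.coordinates, kind="corrected_pca")


@dataclass
class DEResult:
    """Per-gene DE table for one contrast."""

    table: pd.DataFrame  # index gene; columns: log2_fold_change, p_value, fdr,
    #                      detection_rate_<group> per group, tested

    def significant(self, min_fold: float = 2.0, max_fdr: float = 0.05) -> list[str]:
        return fold_change_filter(self, min_fold, max_fdr)


def mnn_correct(
    batches: list[EmbeddingMatrix],
    batch_names: list | None = None,
    k: int = 20,
    sigma: float | None = None,
    n_iter: int = 1,
) -> CorrectedSpace:
    """Sequential MNN correction of batches sharing a PC basis.

    Batches are merged in order of decreasing size; the first (largest) is
    the fixed reference.  For each further batch, mutual k-nearest-neighbor
    pairs with the current reference define per-pair correction vectors
    (reference minus query); each query cell is shifted by the
    Gaussian-weighted average of these vectors, with kernel bandwidth
    ``sigma`` in query space (default 0.1 x the RMS pairwise distance of
    the reference).  Among a query cell's mutual pairs only the closest is
    kept (the surplus pairs of a cell carry a systematic shortfall in the
    offset direction and would dilute the correction).  ``n_iter`` > 1
    repeats the pair-and-shift step on the corrected query; the reported
    pairs are those of the final pass.
    """
    if not batches:
        raise ParameterError("no batches given")
    if batch_names is None:
        batch_names = list(range(len(batches)))
    order = sorted(range(len(batches)), key=lambda i: -batches[i].coordinates.shape[0])

    ref_coords = batches[order[0]].coordinates.copy()
    ref_cells = list(batches[order[0]].cells)
    ref_batch = [batch_names[order[0]]] * len(ref_cells)
    all_pairs: list[tuple[int, int]] = []

    from scipy.spatial.distance import cdist

    for bi in order[1:]:
        q = batches[bi].coordinates.copy()
        pairs = np.zeros((0, 2), dtype=int)
        for _ in range(max(1, n_iter)):
            # pair on batch-mean-centered coordinates so a bulk shift cannot
            # divert the matching; corrections are still applied in raw space
            ref_c = ref_coords - ref_coords.mean(axis=0, keepdims=True)
            q_c = q - q.mean(axis=0, keepdims=True)
            pairs = _mutual_pairs(ref_c, q_c, k)
            if not pairs.size:
                raise ParameterError(
                    f"no mutual nearest-neighbor pairs between batch {batch_names[bi]!r} "
                    "and the reference; try a larger k"
                )
            bw = 0.1 * _rms_pairwise(ref_coords) if sigma is None else sigma
            pd = np.linalg.norm(ref_c[pairs[:, 0]] - q_c[pairs[:, 1]], axis=1)
            best: dict[int, int] = {}
            for p, (_, j) in enumerate(pairs):
                if j not in best or pd[p] < pd[best[j]]:
                    best[j] = p
            pairs = pairs[sorted(best.values())]
            diffs = ref_coords[pairs[:, 0]] - q[pairs[:, 1]]
            anchors = q[pairs[:, 1]]
            # Gaussian-weighted average of pair vectors per query cell
            d2 = cdist(q, anchors, "sqeuclidean")
            w = np.exp(-d2 / (2 * bw ** 2))
            wsum = w.sum(axis=1, keepdims=True)
            w = np.where(wsum > 0, w / np.maximum(wsum, 1e-300), 1.0 / len(anchors))
            q = q + w @ diffs
        corrected = q

        base = len(ref_cells)
        all_pairs.extend([(int(r), base + int(c)) for r, c in pairs])
        ref_coords = np.vstack([ref_coords, corrected])
        ref_cells.extend(batches[bi].cells)
        ref_batch.extend([batch_names[bi]] * len(batches[bi].cells))

    return CorrectedSpace(ref_cells, ref_coords, np.asarray(ref_batch, dtype=object), all_pairs)


def _mutual_pairs(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """(i, j) pairs with a_i among b_j's k-NN in `a` and vice versa."""
    ka = min(k, a.shape[0])
    kb = min(k, b.shape[0])
    nn_ab = NearestNeighbors(n_neighbors=kb).fit(b)
    _, a_to_b = nn_ab.kneighbors(a)     # for each a_i, its kb neighbors in b
    nn_ba = NearestNeighbors(n_neighbors=ka).fit(a)
    _, b_to_a = nn_ba.kneighbors(b)
    b_sets = [set(row) for row in b_to_a]
    pairs = [(i, j) for i in range(a.shape[0]) for j in a_to_b[i] if i in b_sets[j]]
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def _rms_pairwise(x: np.ndarray, max_n: int = 500, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    idx = rng.choice(x.shape[0], size=min(max_n, x.shape[0]), replace=False)
    sub = x[idx]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    iu = np.triu_indices_from(d2, k=1)
    return float(np.sqrt(d2[iu].mean()))


def knn_classify(
    space: CorrectedSpace | EmbeddingMatrix,
    reference_mask: np.ndarray,
    reference_labels: np.ndarray,
    k: int = 20,
) -> np.ndarray:
    """Transfer labels to unlabeled cells by k-NN majority vote.

    ``reference_mask`` marks labeled cells; ``reference_labels`` gives their
    types (aligned with the masked cells).  Ties are broken by the smallest
    mean distance among the tied classes.
    """
    coords = space.coordinates
    reference_mask = np.asarray(reference_mask, dtype=bool)
    ref = coords[reference_mask]
    qry = coords[~reference_mask]
    labels = np.asarray(reference_labels, dtype=object)
    if labels.shape[0] != ref.shape[0]:
        raise ParameterError("reference_labels must align with the masked reference cells")
    if k > ref.shape[0]:
        raise ParameterError(f"k={k} exceeds the {ref.shape[0]} reference cells")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(qry)
    out = np.empty(qry.shape[0], dtype=object)
    for i in range(qry.shape[0]):
        neigh = labels[idx[i]]
        classes, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        tied = classes[counts == top]
        if tied.size == 1:
            out[i] = tied[0]
        else:
            mean_d = {c: dist[i][neigh == c].mean() for c in tied}
            out[i] = min(mean_d, key=mean_d.get)
    return out


# ---------------------------------------------------------------------------
# differential expression


def _moment_dispersions(x: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Within-group method-of-moments NB dispersion per gene, trend-shrunk.

    Normalized counts y = x / sf are pooled within groups; for each group
    phi = (s^2 - mean) / mean^2 and the size-weighted average across groups
    is shrunk (75% weight) toward a robust a + b/mu trend over genes.
    """
    y = x / sf[None, :]
    uniq = np.unique(groups)
    phis = np.zeros(x.shape[0])
    wsum = 0.0
    for g in uniq:
        m = groups == g
        n = int(m.sum())
        mu = y[:, m].mean(axis=1)
        s2 = y[:, m].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(mu > 0, (s2 - mu) / mu ** 2, 0.0)
        phis += n * np.clip(phi_g, 0.0, 10.0)
        wsum += n
    raw = phis / wsum
    mu_all = y.mean(axis=1)
    ok = mu_all > 0
    if ok.sum() >= 10:
        a, b = _robust_trend_fit(mu_all[ok], raw[ok])
        trend = np.clip(a + b / np.maximum(mu_all, 1e-9), 1e-4, 10.0)
    else:
        trend = np.full(x.shape[0], max(raw.mean(), 1e-4))
    shrunk = 0.25 * raw + 0.75 * trend
    return np.clip(shrunk, 1e-4, 10.0)


def differential_expression(
    counts: CountMatrix,
    groups: np.ndarray,
    size_factors: np.ndarray | None = None,
    use_detection_rate: bool = True,
) -> DEResult:
    """Per-gene NB GLM likelihood-ratio test between two groups.

    The design is ``~ group + detection_rate`` where the detection rate is
    the centered per-cell fraction of detected genes; offsets are log size
    factors (library-size factors by default).  The log2 fold change is the
    group coefficient of the full model.  Genes with zero counts in all
    cells are skipped and flagged.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ParameterError("differential_expression expects exactly 2 groups; "
                             "use pairwise contrasts for multi-group designs")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 cells")
    x = counts.counts
    if size_factors is None:
        size_factors = library_size_factors(counts).factors
    offset = np.log(size_factors)
    det_rate = (x > 0).mean(axis=0)
    det_rate = det_rate - det_rate.mean()
    group_ind = (groups == uniq[1]).astype(float)

    design_full = np.column_stack([np.ones_like(group_ind), group_ind])
    design_null = design_full[:, :1]
    if use_detection_rate:
        design_full = np.column_stack([design_full, det_rate])
        design_null = np.column_stack([design_null, det_rate])

    phi = _moment_dispersions(x, size_factors, groups)
    n_genes = x.shape[0]
    l2fc = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    tested = np.zeros(n_genes, dtype=bool)
    for g in range(n_genes):
        y = x[g]
        if y.sum() == 0:
            continue
        fam = sm.families.NegativeBinomial(alpha=float(phi[g]))
        try:
            full = sm.GLM(y, design_full, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            null = sm.GLM(y, design_null, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
        except Exception:
            continue
        lrt = 2.0 * (full.llf - null.llf)
        pval[g] = stats.chi2.sf(max(lrt, 0.0), df=1)
        l2fc[g] = full.params[1] / np.log(2.0)
        tested[g] = True

    fdr = np.full(n_genes, np.nan)
    if tested.any():
        fdr[tested] = _bh(pval[tested])
    table = pd.DataFrame(
        {"log2_fold_change": l2fc, "p_value": pval, "fdr": fdr, "tested": tested},
        index=pd.Index(counts.genes, name="gene"),
    )
    for g in uniq:
        m = groups == g
        table[f"detection_rate_{g}"] = (x[:, m] > 0).mean(axis=1)
    return DEResult(table)


def _bh(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def fold_change_filter(
    de: DEResult | list[DEResult],
    min_fold: float = 2.0,
    max_fdr: float = 0.05,
) -> list[str]:
    """Genes with |L2FC| > log2(min_fold) and FDR < max_fdr, both strict.

    For a list of contrasts ("any comparison" semantics), a gene passes if
    it qualifies in at least one of them.
    """
    results = de if isinstance(de, list) else [de]
    thr = np.log2(min_fold)
    passing: list[str] = []
    seen: set[str] = set()
    for res in results:
        t = res.table
        ok = t["tested"] & (t["log2_fold_change"].abs() > thr) & (t["fdr"] < max_fdr)
        for g in t.index[ok]:
            if g not in seen:
                seen.add(g)
                passing.append(g)
    return passing
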