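"""Count smoothing, normalization, variance-stabilization, HVG selection, PCA.

The preprocessing chain applied to a QC-filtered UMI matrix is:

1. **kNN smoothing** — each cell's raw profile is replaced by the sum over
   itself and its *k* nearest neighbors (Euclidean distance in the leading
   principal components of median-normalized, square-root-stabilized counts,
   with a small seeded dither applied before the neighbor search).  The
   smoothed matrix is rescaled by a single global factor so its grand total
   equals the input's.
2. **Size-factor normalization** — pool-and-deconvolve estimation: summed
   pool profiles are compared against the average cell, yielding linear
   equations in the per-cell factors which are solved by least squares
   (library-size fallback when under-determined); factors are rescaled to
   mean 1.
3. **Freeman–Tukey transform** — ``FT(x) = sqrt(x) + sqrt(x + 1)``, the
   classical variance-stabilizer for counts.
4. **HVG selection** — per-gene CV² against an ``a + b/mu`` technical trend
   fitted by iteratively reweighted least squares; the top fraction by
   observed/fitted CV² ratio is kept, after excluding stress-marker and
   ribosomal genes.
5. **PCA** with a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import lsqr
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, EmbeddingMatrix, ExpressionMatrix


class ParameterError(ValueError):
    pass


@dataclass
class SizeFactors:
    """Per-cell positive scale factors, rescaled to mean 1."""

    cells: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")


@dataclass
class HVGResult:
    """Per-gene variability table and the selected highly-variable set."""

    table: pd.DataFrame  # index gene; columns mean, cv2, trend, hvg_score,
    #                      eligible, selected
    selected: list[str]


def _sign_fixed_pca(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores/loadings with each loading's largest entry positive.

    ``x`` is observations x features; returns (scores, loadings) with
    loadings of shape (features, n_components).
    """
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    v = vt[:n_components].T  # (features, k)
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    scores = xc @ v
    return scores, v


def knn_smooth(
    counts: CountMatrix,
    k: int = 10,
    n_pcs: int = 10,
    dither: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Sum each cell's counts with its *k* nearest neighbors.

    Neighbors are found by Euclidean distance in the first ``n_pcs``
    principal components of median-normalized, square-root-stabilized
    counts; seeded uniform jitter of amplitude ``dither`` x per-component
    range is added to the coordinates before the search (it never alters
    the summed profiles).  The summed matrix is rescaled by one global
    factor so the grand total is conserved, then rounded back to integers.

    ``k = 0`` returns the input unchanged.
    """
    if k < 0 or k >= counts.n_cells:
        raise ParameterError(f"k must satisfy 0 <= k < n_cells ({counts.n_cells})")
    if k == 0:
        return CountMatrix(list(counts.genes), list(counts.cells), counts.counts.copy(),
                           batch=None if counts.batch is None else counts.batch.copy())
    x = counts.counts.T.astype(float)  # cells x genes
    totals = x.sum(axis=1)
    med = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scaled = x * (med / np.maximum(totals, 1e-12))[:, None]
    stab = np.sqrt(scaled)
    n_pcs = min(n_pcs, min(stab.shape) - 1) or 1
    scores, _ = _sign_fixed_pca(stab, n_pcs)
    if dither > 0:
        rng = np.random.default_rng(seed)
        rng_range = scores.max(axis=0) - scores.min(axis=0)
        scores = scores + rng.uniform(-1, 1, scores.shape) * (dither * rng_range)[None, :]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, nbr = nn.kneighbors(scores)
    summed = counts.counts[:, nbr].sum(axis=2)  # (genes, cells)
    total_in = int(counts.counts.sum())
    scaled2 = summed * (total_in / summed.sum())
    # largest-remainder rounding: integral output, grand total conserved exactly
    flat = scaled2.ravel()
    floor = np.floor(flat)
    deficit = total_in - int(floor.sum())
    if deficit > 0:
        top = np.argpartition(-(flat - floor), deficit - 1)[:deficit]
        floor[top] += 1
    smoothed = floor.astype(np.int64).reshape(scaled2.shape)
    return CountMatrix(list(counts.genes), list(counts.cells), smoothed,
                       batch=None if counts.batch is None else counts.batch.copy())


def estimate_size_factors(
    counts: CountMatrix,
    pool_sizes: tuple[int, ...] = (21, 41, 61),
) -> SizeFactors:
    """Pool-and-deconvolve size factors.

    Cells are arranged on a ring ordered by library size; for every pool
    size *s* and start position, the pooled profile's median ratio to the
    average cell gives one linear equation in the member cells' factors.
    The sparse system is solved by least squares with a weak ridge tying
    each factor to its library-size estimate (this also resolves the
    under-determined case).  Factors are rescaled to mean 1.
    """
    n = counts.n_cells
    if n < 2:
        raise ParameterError("need at least 2 cells")
    x = counts.counts.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ParameterError("cells with zero total cannot be normalized")
    lib_sf = lib / lib.mean()
    ref = x.mean(axis=1)  # average cell profile
    use = ref > 0
    pool_sizes = tuple(min(s, n) for s in pool_sizes)

    order = np.argsort(lib)
    # interleave smallest/largest so ring neighborhoods mix depths
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]

    s_max = max(pool_sizes)
    ext = np.concatenate([ring, ring[:s_max]])
    cs = np.zeros((use.sum(), n + s_max + 1))
    cs[:, 1:] = np.cumsum(x[np.ix_(use, ext)], axis=1)
    refu = ref[use]

    rows, cols, vals, b = [], [], [], []
    r = 0
    for s in sorted(set(pool_sizes)):
        for start in range(n):
            members = ext[start:start + s]
            pooled = cs[:, start + s] - cs[:, start]
            ratio = np.median(pooled / refu)
            rows.extend([r] * s)
            cols.extend(members.tolist())
            vals.extend([1.0] * s)
            b.append(ratio)
            r += 1
    # weak anchor to library-size factors; also sets the overall scale
    w = 0.05
    for i in range(n):
        rows.append(r)
        cols.append(i)
        vals.append(w)
        b.append(w * lib_sf[i])
        r += 1
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n))
    sol = lsqr(a, np.asarray(b), atol=1e-10, btol=1e-10)[0]
    if np.any(sol <= 0):
        raise ValueError(
            "pool deconvolution produced non-positive factors; "
            "use library-size factors (library_size_factors) instead"
        )
    sol = sol / sol.mean()
    return SizeFactors(list(counts.cells), sol)


def library_size_factors(counts: CountMatrix) -> SizeFactors:
    """Library-size (total count) factors, rescaled to mean 1."""
    lib = counts.total_per_cell().astype(float)
    if np.any(lib <= 0):
        raise ParameterError("cells with zero total cannot be normalized")
    return SizeFactors(list(counts.cells), lib / lib.mean())


def normalize(counts: CountMatrix, sf: SizeFactors) -> ExpressionMatrix:
    """Divide each cell's counts by its size factor."""
    if list(sf.cells) != list(counts.cells):
        raise ParameterError("size factors do not match the matrix cells")
    vals = counts.counts / sf.factors[None, :]
    return ExpressionMatrix(list(counts.genes), list(counts.cells), vals, "normalized")


def freeman_tukey(x: ExpressionMatrix) -> ExpressionMatrix:
    """Freeman–Tukey variance-stabilizing transform, sqrt(x) + sqrt(x + 1)."""
    if np.any(x.values < 0):
        raise ValueError("Freeman-Tukey transform requires non-negative values")
    vals = np.sqrt(x.values) + np.sqrt(x.values + 1.0)
    return ExpressionMatrix(list(x.genes), list(x.cells), vals, "freeman_tukey")


def _robust_trend_fit(mean: np.ndarray, cv2: np.ndarray, n_iter: int = 20) -> tuple[float, float]:
    """Fit cv2 ~ a + b/mean by Tukey-biweight IRLS; returns (a, b)."""
    z = 1.0 / mean
    design = np.column_stack([np.ones_like(z), z])
    w = np.ones_like(z)
    a_b = np.linalg.lstsq(design, cv2, rcond=None)[0]
    for _ in range(n_iter):
        resid = cv2 - design @ a_b
        s = np.median(np.abs(resid)) * 1.4826 + 1e-12
        u = resid / (4.685 * s)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() < 2:
            break
        wd = design * w[:, None]
        new = np.linalg.lstsq(wd.T @ design, wd.T @ cv2, rcond=None)[0]
        if np.allclose(new, a_b, rtol=1e-10, atol=1e-12):
            a_b = new
            break
        a_b = new
    return float(a_b[0]), float(a_b[1])


def select_hvg(
    x: ExpressionMatrix,
    fraction: float = 0.05,
    exclude: list[str] | None = None,
    min_mean: float = 0.0,
) -> HVGResult:
    """Select highly variable genes by excess CV² over an a + b/mu trend.

    CV² is computed per gene on normalized expression; the technical trend
    ``CV²_fit(mu) = a + b/mu`` is fitted robustly over genes with positive
    mean, and genes are ranked by ``hvg_score = CV² / CV²_fit``.  The top
    ``ceil(fraction x n_eligible)`` eligible genes are selected; genes on
    the exclusion lists (typically stress markers and ribosomal genes) and
    genes with mean <= ``min_mean`` (when > 0) are never selected but still
    receive scores.
    """
    if x.n_cells < 2:
        raise ParameterError("need at least 2 cells")
    vals = x.values
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, var / mean ** 2, np.nan)
    fit_mask = mean > 0
    a, b = _robust_trend_fit(mean[fit_mask], cv2[fit_mask])
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = a + b / mean
        score = np.where(fit_mask & (trend > 0), cv2 / trend, np.nan)

    excluded = set(s.upper() for s in (exclude or []))
    eligible = fit_mask & ~np.isnan(score)
    eligible &= np.array([g.upper() not in excluded for g in x.genes])
    if min_mean > 0:
        eligible &= mean > min_mean

    n_el = int(eligible.sum())
    n_req = int(np.ceil(fraction * n_el))
    if n_el == 0:
        warnings.warn("no eligible genes for HVG selection")
        chosen: list[int] = []
    else:
        el_idx = np.flatnonzero(eligible)
        order = el_idx[np.argsort(-score[el_idx], kind="stable")]
        chosen = order[:n_req].tolist()
    sel = np.zeros(x.n_genes, dtype=bool)
    sel[chosen] = True
    table = pd.DataFrame(
        {"mean": mean, "cv2": cv2, "trend": trend, "hvg_score": score,
         "eligible": eligible, "selected": sel},
        index=pd.Index(x.genes, name="gene"),
    )
    return HVGResult(table, [x.genes[i] for i in sorted(chosen)])


def pca(x: ExpressionMatrix, n_components: int, genes: list[str] | None = None) -> EmbeddingMatrix:
    """Centered PCA of cells over a gene subset, with deterministic signs.

    Each loading vector's largest-magnitude entry is made positive, so
    repeated runs are bit-identical.
    """
    if genes is not None:
        if len(genes) == 0:
            raise ParameterError("empty gene subset")
        idx = x.gene_index(genes)
        if idx.size == 0:
            raise ParameterError("none of the requested genes are present")
        vals = x.values[idx]
    else:
        vals = x.values
    data = vals.T  # cells x genes
    if n_components > min(data.shape):
        raise ParameterError("n_components exceeds matrix rank bound")
    scores, _ = _sign_fixed_pca(data, n_components)
    return EmbeddingMatrix(list(x.cells), scores, kind="pca")
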