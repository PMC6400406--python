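"""Gene-set enrichment by one-sided Fisher's exact test.

Given a differentially expressed gene set, a disease-associated gene list
(e.g. kidney-trait GWAS genes, with a lung-trait list as negative control),
and a gene universe (by default all genes detected in the experiment), the
2x2 overlap table is tested for over-representation with the one-sided
(greater) Fisher's exact test — the hypergeometric upper tail
``P(X >= observed overlap)`` — and p-values across tests are adjusted by
Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EnrichmentResult:
    """One-sided Fisher's exact test of a 2x2 gene-overlap table."""

    overlap: int          # DE ∩ list
    de_only: int          # DE \ list
    list_only: int        # list \ DE
    neither: int
    odds_ratio: float     # inf when a denominator margin cell is 0
    p_value: float
    universe_size: int

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.overlap, self.de_only], [self.list_only, self.neither]])


def fisher_enrichment(
    de_genes: set[str] | list[str],
    disease_genes: set[str] | list[str],
    universe: set[str] | list[str],
) -> EnrichmentResult:
    """Test whether ``disease_genes`` are enriched in ``de_genes``.

    Genes outside the universe are dropped with a warning.  The one-sided p
    is the hypergeometric tail probability of an overlap at least as large
    as observed.
    """
    universe = set(g.upper() for g in universe)
    if not universe:
        raise ValueError("empty gene universe")
    de = set(g.upper() for g in de_genes)
    dl = set(g.upper() for g in disease_genes)
    dropped = (de - universe) | (dl - universe)
    if dropped:
        warnings.warn(f"{len(dropped)} genes outside the universe were dropped")
    de &= universe
    dl &= universe

    n = len(universe)
    a = len(de & dl)
    b = len(de - dl)
    c = len(dl - de)
    d = n - a - b - c
    # hypergeometric upper tail: P(X >= a) drawing |DE| genes from the universe
    p = float(stats.hypergeom.sf(a - 1, n, len(dl), len(de)))
    odds = float(a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(a, b, c, d, odds, min(p, 1.0), n)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    ``adjusted_(i) = min_{j >= i} p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
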