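"""Per-cell quality control and cell-removal rules.

Droplet scRNA-seq of dissociation-sensitive tissue carries three dominant
artifact classes that must be removed before analysis:

* **low-count cells** — barcodes with fewer than 2,000 transcripts, mostly
  empty or dying droplets;
* **stressed cells** — cells whose transcriptome is dominated by the
  dissociation stress response: more than 10% of UMIs from the 13
  mitochondrial protein-coding genes or more than 5% from a curated list of
  dissociation-induced stress genes;
* **red blood cells** — more than 1% of UMIs from hemoglobin genes
  (HBB, HBA1, HBA2).

Each cell receives exactly one flag, with precedence
low_count > stressed > red_blood_cell > retained, so the four classes
partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneListRegistry

FLAGS = ("retained", "low_count", "stressed", "red_blood_cell")


class ConfigurationError(ValueError):
    pass


@dataclass
class CellQCReport:
    """Per-cell totals, list-expression fractions, and removal flags."""

    table: pd.DataFrame  # index = barcode; columns: total_umi, mito_fraction,
    #                      stress_fraction, hemoglobin_fraction, flag

    def counts_by_flag(self) -> dict[str, int]:
        vc = self.table["flag"].value_counts()
        return {f: int(vc.get(f, 0)) for f in FLAGS}


def _list_fraction(counts: CountMatrix, registry: GeneListRegistry, name: str,
                   totals: np.ndarray) -> np.ndarray:
    symbols = registry[name]
    idx = counts.gene_index(symbols)
    if idx.size == 0:
        raise ConfigurationError(f"no genes of list {name!r} present in the matrix")
    s = counts.counts[idx].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, s / np.maximum(totals, 1), 0.0)
    return frac


def compute_cell_qc(
    counts: CountMatrix,
    registry: GeneListRegistry,
    min_umi: int = 2000,
    max_mito: float = 0.10,
    max_stress: float = 0.05,
    max_hb: float = 0.01,
) -> CellQCReport:
    """Compute per-cell QC metrics and removal flags.

    Fractions are list-gene UMI sums over the cell's total UMI (denominator
    before any gene exclusion); a zero-total cell has all fractions defined
    as 0 and is flagged ``low_count``.  Thresholds follow the strict
    inequalities of the removal rules: cells with total < ``min_umi`` are
    low_count; cells with mito fraction > ``max_mito`` OR stress fraction
    > ``max_stress`` are stressed; cells with hemoglobin fraction >
    ``max_hb`` are red blood cells.
    """
    _validate_thresholds(min_umi, max_mito, max_stress, max_hb)
    totals = counts.total_per_cell()
    mito = _list_fraction(counts, registry, "mitochondrial", totals)
    stress = _list_fraction(counts, registry, "stress_markers", totals)
    hb = _list_fraction(counts, registry, "hemoglobin", totals)

    flag = np.full(counts.n_cells, "retained", dtype=object)
    rbc = hb > max_hb
    flag[rbc] = "red_blood_cell"
    stressed = (mito > max_mito) | (stress > max_stress)
    flag[stressed] = "stressed"
    low = totals < min_umi
    flag[low] = "low_count"

    table = pd.DataFrame(
        {
            "total_umi": totals,
            "mito_fraction": mito,
            "stress_fraction": stress,
            "hemoglobin_fraction": hb,
            "flag": flag,
        },
        index=pd.Index(counts.cells, name="cell"),
    )
    return CellQCReport(table)


def _validate_thresholds(min_umi, max_mito, max_stress, max_hb):
    if min_umi < 0:
        raise ConfigurationError("min_umi must be >= 0")
    for name, v in (("max_mito", max_mito), ("max_stress", max_stress), ("max_hb", max_hb)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{name} must lie in [0, 1]")


def filter_cells(
    counts: CountMatrix,
    qc: CellQCReport,
    min_umi: int = 2000,
    max_mito: float = 0.10,
    max_stress: float = 0.05,
    max_hb: float = 0.01,
) -> tuple[CountMatrix, dict[str, int]]:
    """Apply the removal rules: return the retained submatrix and class counts.

    Flags are (re)derived from the report's metric columns at the given
    thresholds, so a report computed once can be filtered at several
    settings.  The class counts always satisfy
    ``retained + low_count + stressed + red_blood_cell == n_cells``.
    """
    _validate_thresholds(min_umi, max_mito, max_stress, max_hb)
    if list(qc.table.index) != list(counts.cells):
        raise ConfigurationError("QC report does not match the count matrix cells")
    t = qc.table
    flag = np.full(len(t), "retained", dtype=object)
    flag[(t["hemoglobin_fraction"] > max_hb).to_numpy()] = "red_blood_cell"
    flag[((t["mito_fraction"] > max_mito) | (t["stress_fraction"] > max_stress)).to_numpy()] = "stressed"
    flag[(t["total_umi"] < min_umi).to_numpy()] = "low_count"
    qc.table = t.assign(flag=flag)
    summary = qc.counts_by_flag()
    return counts.subset_cells(flag == "retained"), summary
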