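"""Core data containers and file I/O.

The in-memory currency of the pipeline is a small set of dataclasses:

* :class:`CountMatrix` — genes x cells non-negative integer UMI counts,
* :class:`ExpressionMatrix` — real-valued genes x cells matrix with a tag
  recording which transform produced it,
* :class:`GeneListRegistry` — named curated gene-symbol lists (mitochondrial,
  stress, hemoglobin, ribosomal, ...) that drive filters and scores,
* :class:`EmbeddingMatrix` — cells x components coordinates (PCA etc.).

On disk the canonical interchange format for counts is MatrixMarket MTX with
genes as rows and cells as columns, accompanied by ``genes.tsv`` and
``barcodes.tsv`` (one symbol/barcode per line); dense CSV is accepted for
small fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# The 13 protein-coding mitochondrial genes used for the mito-fraction QC rule.
MITOCHONDRIAL_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

# Hemoglobin genes used for the red-blood-cell rule.
HEMOGLOBIN_GENES = ("HBB", "HBA1", "HBA2")


def _check_unique(items: Sequence[str], what: str) -> None:
    if len(set(items)) != len(items):
        seen: set[str] = set()
        for it in items:
            if it in seen:
                raise FormatError(f"duplicate {what}: {it!r}")
            seen.add(it)


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray  # (n_genes, n_cells) integer
    batch: np.ndarray | None = None  # per-cell batch label

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.cells, "cell barcode")
        if np.any(self.counts < 0):
            g, c = np.argwhere(self.counts < 0)[0]
            raise FormatError(f"negative count at gene {self.genes[g]!r}, cell {self.cells[c]!r}")
        if not np.allclose(self.counts, np.round(self.counts)):
            g, c = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))[0]
            raise FormatError(f"non-integer count at gene {self.genes[g]!r}, cell {self.cells[c]!r}")
        self.counts = np.round(self.counts).astype(np.int64)
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.shape != (len(self.cells),):
                raise FormatError("batch labels must be one per cell")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_per_cell(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[:, idx],
            batch=None if self.batch is None else self.batch[idx],
        )

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        """Row indices of ``symbols`` present in the matrix (case-insensitive)."""
        lookup = {g.upper(): i for i, g in enumerate(self.genes)}
        found = [lookup[s.upper()] for s in symbols if s.upper() in lookup]
        missing = [s for s in symbols if s.upper() not in lookup]
        if missing:
            warnings.warn(f"{len(missing)} gene symbols not in matrix: {missing[:5]}")
        return np.asarray(found, dtype=int)


@dataclass
class ExpressionMatrix:
    """Real-valued genes x cells matrix with a transform tag."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    transform_tag: str = "raw"  # raw | normalized | freeman_tukey | log1p

    _TAGS = ("raw", "normalized", "freeman_tukey", "log1p")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise FormatError("values shape does not match genes x cells")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if self.transform_tag not in self._TAGS:
            raise FormatError(f"unknown transform_tag {self.transform_tag!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        lookup = {g.upper(): i for i, g in enumerate(self.genes)}
        return np.asarray([lookup[s.upper()] for s in symbols if s.upper() in lookup], dtype=int)


@dataclass
class GeneListRegistry:
    """Named curated gene-symbol lists.

    Symbols are stored uppercase and deduplicated (first occurrence wins);
    lookups are case-insensitive.
    """

    lists: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, symbols in self.lists.items():
            seen: list[str] = []
            have: set[str] = set()
            for s in symbols:
                u = str(s).upper()
                if u not in have:
                    have.add(u)
                    seen.append(u)
            clean[str(name)] = seen
        self.lists = clean

    def __getitem__(self, name: str) -> list[str]:
        if name not in self.lists:
            raise KeyError(f"no gene list named {name!r}; available: {sorted(self.lists)}")
        if not self.lists[name]:
            raise ValueError(f"gene list {name!r} is empty")
        return self.lists[name]

    def __contains__(self, name: str) -> bool:
        return name in self.lists

    def get(self, name: str, default: list[str] | None = None) -> list[str] | None:
        return self.lists.get(name, default)


@dataclass
class EmbeddingMatrix:
    """Cells x components coordinate matrix (PCA, corrected PCA, tSNE)."""

    cells: list[str]
    coordinates: np.ndarray  # (n_cells, n_components)
    kind: str = "pca"  # pca | corrected_pca | tsne

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[0] != len(self.cells):
            raise FormatError("coordinates must be n_cells x n_components")
        if self.coordinates.shape[1] < 1:
            raise FormatError("need at least one component")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("coordinates must be finite")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# count-matrix I/O


def read_count_matrix(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Read a count matrix from disk.

    ``format='mtx'``: *path* is either the ``.mtx`` file or a directory
    containing ``matrix.mtx``; ``genes.tsv`` and ``barcodes.tsv`` must sit
    next to the matrix file.  Genes are rows, cells are columns (1-based on
    disk, 0-based in memory).

    ``format='csv'``: dense CSV with gene symbols as the index column and
    barcodes as the header.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(list(df.index), list(df.columns), df.to_numpy())
    if format != "mtx":
        raise ValueError(f"unknown format {format!r}")

    if path.is_dir():
        mtx_path = path / "matrix.mtx"
    else:
        mtx_path = path
    if not mtx_path.exists():
        raise FileNotFoundError(mtx_path)
    try:
        mat = spio.mmread(mtx_path)
    except Exception as exc:  # pragma: no cover - scipy message forwarded
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = np.asarray(sparse.coo_matrix(mat).todense())

    genes = _read_tsv_column(mtx_path.parent / "genes.tsv")
    cells = _read_tsv_column(mtx_path.parent / "barcodes.tsv")
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{mtx_path} declares {mat.shape[0]} rows but genes.tsv has {len(genes)} symbols"
        )
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"{mtx_path} declares {mat.shape[1]} columns but barcodes.tsv has {len(cells)} barcodes"
        )
    return CountMatrix(genes, cells, mat)


def _read_tsv_column(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split("\t")[0])
    return out


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write *cm* as ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` under *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(cm.counts), field="integer")
    (path / "genes.tsv").write_text("\n".join(cm.genes) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(cm.cells) + "\n")


# ---------------------------------------------------------------------------
# gene lists


def read_gene_lists(path: str | Path) -> GeneListRegistry:
    """Read named gene lists from a CSV (columns ``list,symbol``) or YAML file.

    YAML maps list names to symbol arrays.  Symbols are uppercased and
    deduplicated within each list.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected a mapping of list name -> symbols")
        return GeneListRegistry({str(k): [str(s) for s in v] for k, v in data.items()})
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "list" not in cols or "symbol" not in cols:
        raise FormatError(f"{path}: need 'list' and 'symbol' columns, got {list(df.columns)}")
    lists: dict[str, list[str]] = {}
    for name, sub in df.groupby(cols["list"], sort=False):
        lists[str(name)] = [str(s) for s in sub[cols["symbol"]]]
    return GeneListRegistry(lists)


def write_gene_lists(registry: GeneListRegistry, path: str | Path) -> None:
    rows = [(name, s) for name, syms in registry.lists.items() for s in syms]
    pd.DataFrame(rows, columns=["list", "symbol"]).to_csv(path, index=False)


def read_polyline(path: str | Path) -> np.ndarray:
    """Read an (n, 2) polyline/polygon from JSON ``[[r, c], ...]`` or CSV with
    ``row,col`` columns.  Coordinates are pixel-center, 0-based, (row, col)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        pts = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "row" in cols and "col" in cols:
            pts = df[[cols["row"], cols["col"]]].to_numpy(dtype=float)
        else:
            pts = df.iloc[:, :2].to_numpy(dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise FormatError(f"{path}: polyline needs >= 2 points with 2 coordinates each")
    return pts
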