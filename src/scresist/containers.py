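"""Core in-memory containers for the pipeline.

The pipeline works on a genes x cells orientation throughout: rows are
genes, columns are cell barcodes.  Two containers carry the data between
stages:

``CountMatrix``
    Raw UMI counts (non-negative integers) with per-gene mitochondrial /
    ribosomal flags derived from gene-symbol prefixes.

``NormalizedMatrix``
    Log-normalized expression values ``ln(1 + scale * count / total)``
    together with the per-cell size factors used, after removal of
    mitochondrial and ribosomal genes.

Per-cell metadata (line, condition, patient, timepoint, QC metrics,
cluster labels, similarity scores) travels as a plain :class:`pandas.DataFrame`
indexed by barcode — the "cell annotation" table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "MITO_PREFIXES",
    "RIBO_PREFIXES",
]

MITO_PREFIXES = ("MT-",)
RIBO_PREFIXES = ("RPL", "RPS")


def flag_genes(
    genes,
    mito_prefixes=MITO_PREFIXES,
    ribo_prefixes=RIBO_PREFIXES,
) -> pd.DataFrame:
    """Per-gene mito/ribo flags from case-insensitive symbol prefixes."""
    upper = pd.Index(genes).str.upper()
    is_mito = upper.str.startswith(tuple(p.upper() for p in mito_prefixes))
    is_ribo = upper.str.startswith(tuple(p.upper() for p in ribo_prefixes))
    return pd.DataFrame(
        {"is_mito": np.asarray(is_mito), "is_ribo": np.asarray(is_ribo)},
        index=pd.Index(genes, name="gene"),
    )


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix.

    Parameters
    ----------
    genes
        Ordered unique gene symbols (rows).
    cells
        Ordered unique cell barcodes (columns).
    counts
        ``(n_genes, n_cells)`` array of non-negative integers.
    gene_flags
        Optional DataFrame with boolean columns ``is_mito`` / ``is_ribo``
        indexed like ``genes``; derived from symbol prefixes when omitted.
    """

    genes: pd.Index
    cells: pd.Index
    counts: np.ndarray
    gene_flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="barcode")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            dups = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if not self.cells.is_unique:
            raise ValueError("duplicate cell barcodes")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        if self.gene_flags is None:
            self.gene_flags = flag_genes(self.genes)
        else:
            self.gene_flags = self.gene_flags.reindex(self.genes)

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_counts(self) -> np.ndarray:
        """Per-cell library size (over all genes, mito/ribo included)."""
        return self.counts.sum(axis=0)

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's counts mapping to mitochondrial genes."""
        total = self.total_counts().astype(float)
        mito = self.counts[self.gene_flags["is_mito"].to_numpy()].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / total, 0.0)
        return frac

    def subset_cells(self, barcodes) -> "CountMatrix":
        idx = self.cells.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            raise KeyError("unknown barcode(s) in subset")
        return CountMatrix(
            self.genes, pd.Index(barcodes), self.counts[:, idx], self.gene_flags
        )

    def subset_genes(self, symbols) -> "CountMatrix":
        idx = self.genes.get_indexer(pd.Index(symbols))
        if (idx < 0).any():
            raise KeyError("unknown gene(s) in subset")
        return CountMatrix(
            pd.Index(symbols),
            self.cells,
            self.counts[idx],
            self.gene_flags.iloc[idx],
        )


@dataclass
class NormalizedMatrix:
    """Genes x cells log-normalized expression.

    ``values[g, i] = ln(1 + scale * counts[g, i] / total_i)``; mitochondrial
    and ribosomal genes have been dropped, but ``size_factors`` reflect the
    full library of each cell.
    """

    genes: pd.Index
    cells: pd.Index
    values: np.ndarray
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="barcode")
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape inconsistent with gene/cell index")
        if self.size_factors.shape != (len(self.cells),):
            raise ValueError("size_factors must be one scalar per cell")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log-normalized values must be non-negative")
        if self.size_factors.size and self.size_factors.min() <= 0:
            raise ValueError("size factors must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_indexer(self, barcodes) -> np.ndarray:
        idx = self.cells.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            raise KeyError("unknown barcode(s)")
        return idx

    def gene_indexer(self, symbols) -> np.ndarray:
        idx = self.genes.get_indexer(pd.Index(symbols))
        if (idx < 0).any():
            missing = [g for g in symbols if g not in self.genes]
            raise KeyError(f"unknown gene(s): {missing[:5]}")
        return idx

    def subset_genes(self, symbols) -> "NormalizedMatrix":
        idx = self.gene_indexer(symbols)
        return NormalizedMatrix(
            pd.Index(symbols), self.cells, self.values[idx], self.size_factors
        )

    def subset_cells(self, barcodes) -> "NormalizedMatrix":
        idx = self.cell_indexer(barcodes)
        return NormalizedMatrix(
            self.genes, pd.Index(barcodes), self.values[:, idx], self.size_factors[idx]
        )
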