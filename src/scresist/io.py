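"""Readers and writers for the formats the pipeline touches.

Count matrices come in two dialects:

``mtx_triplet``
    10x-style directory triplet: ``matrix.mtx`` (MatrixMarket coordinate,
    genes as rows), ``features.tsv`` (one symbol per line) and
    ``barcodes.tsv`` (one barcode per line).

``tsv_dense``
    Dense TSV with gene symbols in the first column and one header row of
    barcodes.

Gene-set collections use the GMT format (name, description, tab-separated
members).  All result tables are plain TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, NormalizedMatrix, flag_genes

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotation",
    "write_annotation",
    "write_normalized_matrix",
    "read_normalized_matrix",
]


def _collapse_duplicate_genes(genes: pd.Index, counts: np.ndarray):
    """Sum rows sharing a gene symbol, keeping first-occurrence order."""
    if genes.is_unique:
        return genes, counts
    dupes = genes[genes.duplicated()].unique().tolist()
    logger.warning(
        "collapsing %d duplicated gene symbol(s) by summation: %s%s",
        len(dupes),
        ", ".join(dupes[:5]),
        "..." if len(dupes) > 5 else "",
    )
    frame = pd.DataFrame(counts)
    frame["__gene__"] = genes.to_numpy()
    summed = frame.groupby("__gene__", sort=False).sum()
    return pd.Index(summed.index, name="gene"), summed.to_numpy()


def read_count_matrix(path, dialect: str = "mtx_triplet") -> CountMatrix:
    """Read a genes x cells UMI count matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: the directory containing ``matrix.mtx``,
        ``features.tsv`` and ``barcodes.tsv``.  For ``tsv_dense``: the TSV
        file itself.
    dialect
        ``"mtx_triplet"`` or ``"tsv_dense"``.

    Duplicate gene symbols are collapsed by summation (logged); mito/ribo
    flags are set from symbol prefixes (``MT-``; ``RPL``/``RPS``).
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        bars = path / "barcodes.tsv"
        for f in (mtx, feats, bars):
            if not f.exists():
                raise FileNotFoundError(f"mtx_triplet requires {f}")
        counts = scipy.io.mmread(mtx)
        if scipy.sparse.issparse(counts):
            counts = counts.toarray()
        counts = np.asarray(counts)
        genes = pd.Index(
            pd.read_csv(feats, sep="\t", header=None).iloc[:, 0].astype(str)
        )
        cells = pd.Index(
            pd.read_csv(bars, sep="\t", header=None).iloc[:, 0].astype(str)
        )
        if counts.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{mtx}: matrix is {counts.shape} but sidecars give "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
    elif dialect == "tsv_dense":
        table = pd.read_csv(path, sep="\t", index_col=0)
        genes = pd.Index(table.index.astype(str))
        cells = pd.Index(table.columns.astype(str))
        counts = table.to_numpy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if np.issubdtype(counts.dtype, np.floating):
        if not np.allclose(counts, np.round(counts)):
            bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
            raise ValueError(
                f"{path}: non-integer count at gene row {bad[0]}, cell column {bad[1]}"
            )
        counts = np.round(counts).astype(np.int64)
    if counts.size and counts.min() < 0:
        bad = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"{path}: negative count at gene row {bad[0]}, cell column {bad[1]}"
        )
    genes, counts = _collapse_duplicate_genes(genes, counts)
    return CountMatrix(genes, cells, counts, flag_genes(genes))


def write_count_matrix(matrix: CountMatrix, path, dialect: str = "mtx_triplet") -> None:
    """Write a count matrix in either dialect (inverse of :func:`read_count_matrix`)."""
    path = Path(path)
    if dialect == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
        (path / "features.tsv").write_text("\n".join(matrix.genes) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(matrix.cells) + "\n")
    elif dialect == "tsv_dense":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            matrix.counts, index=matrix.genes, columns=matrix.cells
        ).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into ``{name: members}``.

    Members are de-duplicated preserving order.  Empty sets are skipped
    with a warning; duplicate set names raise.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                logger.warning("%s:%d: empty gene set %r skipped", path, lineno, name)
                continue
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Read a per-cell annotation TSV indexed by barcode."""
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="barcode")


def write_normalized_matrix(norm: NormalizedMatrix, path) -> None:
    """Persist a normalized matrix as dense TSV plus a size-factor sidecar."""
    path = Path(path)
    pd.DataFrame(norm.values, index=norm.genes, columns=norm.cells).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    pd.Series(norm.size_factors, index=norm.cells, name="size_factor").to_csv(
        path.with_suffix(path.suffix + ".size_factors"), sep="\t", index_label="barcode"
    )


def read_normalized_matrix(path) -> NormalizedMatrix:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    sf = pd.read_csv(
        path.with_suffix(path.suffix + ".size_factors"), sep="\t", index_col="barcode"
    )["size_factor"]
    return NormalizedMatrix(
        pd.Index(table.index.astype(str)),
        pd.Index(table.columns.astype(str)),
        table.to_numpy(),
        sf.to_numpy(),
    )
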