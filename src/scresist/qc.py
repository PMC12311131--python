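"""Quality control, log-normalization and variable-gene selection.

The QC rules mirror standard droplet scRNA-seq practice for deeply
sequenced cell lines: a gene counts as *expressed* when its size-factor
scaled count reaches a relative-expression threshold in enough cells;
cells are retained when their number of expressed genes falls within an
inclusive band and their mitochondrial count fraction stays at or below a
cap.  Mitochondrial and ribosomal genes are excluded from all downstream
analyses (after normalization; library totals include them, since those
counts are real library mass).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "detect_expressed_genes",
    "filter_cells",
    "lognormalize",
    "top_variable_genes",
]


def detect_expressed_genes(
    counts: CountMatrix,
    rel_expr_threshold: float = 0.1,
    min_cells: int = 10,
) -> pd.Index:
    """Genes whose relative expression reaches the threshold in enough cells.

    Relative expression of gene ``g`` in cell ``i`` is
    ``counts[g, i] / size_factor_i`` with ``size_factor_i =
    total_i / median(total)``.  A gene is expressed iff its relative
    expression is ``>= rel_expr_threshold`` in ``>= min_cells`` cells
    (both boundaries inclusive).
    """
    totals = counts.total_counts().astype(float)
    median_total = float(np.median(totals))
    if median_total == 0:
        logger.warning("all-zero count matrix: no expressed genes")
        return pd.Index([], name="gene")
    size_factors = totals / median_total
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(size_factors > 0, counts.counts / size_factors, 0.0)
    n_qualifying = (rel >= rel_expr_threshold).sum(axis=1)
    keep = n_qualifying >= min_cells
    if not keep.any():
        logger.warning("no gene passes the expressed-gene rule")
    return counts.genes[keep]


def filter_cells(
    counts: CountMatrix,
    expressed_genes: pd.Index,
    min_genes: int = 2000,
    max_genes: int = 7000,
    max_mito: float = 0.10,
):
    """Retain cells by expressed-gene count and mitochondrial fraction.

    ``n_genes_detected`` counts expressed genes with a nonzero count in the
    cell; the mitochondrial fraction uses all counts (mito genes included).
    All three boundaries are inclusive: cells with exactly ``min_genes`` or
    ``max_genes`` detected genes, or a mito fraction exactly at ``max_mito``,
    are retained.

    Returns ``(filtered CountMatrix, qc_report)`` where the report has one
    row per *input* cell with its metrics, pass flag and failure reason.
    """
    expr_idx = counts.genes.get_indexer(pd.Index(expressed_genes))
    if (expr_idx < 0).any():
        raise KeyError("expressed_genes contains symbols absent from the matrix")
    n_detected = (counts.counts[expr_idx] > 0).sum(axis=0)
    totals = counts.total_counts()
    mito_frac = counts.mito_fraction()

    reasons = np.full(counts.n_cells, "", dtype=object)
    reasons[n_detected < min_genes] = "min_genes"
    reasons[n_detected > max_genes] = "max_genes"
    too_mito = (mito_frac > max_mito) & (reasons == "")
    reasons[too_mito] = "max_mito"
    # cells failing both rules report the gene-count rule first
    passed = reasons == ""
    report = pd.DataFrame(
        {
            "n_genes_detected": n_detected,
            "total_counts": totals,
            "mito_fraction": mito_frac,
            "pass": passed,
            "fail_reason": reasons,
        },
        index=counts.cells,
    )
    if not passed.any():
        binding = report.loc[~report["pass"], "fail_reason"].mode().iat[0]
        raise ValueError(
            f"no cell passes QC; the binding constraint is {binding!r}"
        )
    filtered = counts.subset_cells(counts.cells[passed])
    return filtered, report


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Global-scaling log-normalization, then drop mito/ribo genes.

    ``value[g, i] = ln(1 + scale * counts[g, i] / total_i)`` with ``total_i``
    computed over *all* genes (mitochondrial included) before the mito and
    ribosomal rows are removed.  Size factors are stored median-scaled.
    """
    totals = counts.total_counts().astype(float)
    if (totals == 0).any():
        zero = counts.cells[totals == 0][:3].tolist()
        raise ValueError(f"cell(s) with zero total counts: {zero}")
    values = np.log1p(scale * counts.counts / totals[None, :])
    keep = ~(counts.gene_flags["is_mito"] | counts.gene_flags["is_ribo"]).to_numpy()
    return NormalizedMatrix(
        counts.genes[keep],
        counts.cells,
        values[keep],
        totals / float(np.median(totals)),
    )


def top_variable_genes(
    norm: NormalizedMatrix,
    k: int = 2000,
    method: str = "trend",
    window: int | None = None,
) -> list[str]:
    """Rank genes by variance standardized against a mean-variance trend.

    Genes are ordered by expression mean, a centered running median of the
    per-gene variance provides the expected variance at each mean, and
    genes are ranked by the ratio ``variance / trend`` (``method="trend"``)
    or by raw variance (``method="variance"``).  Zero-variance genes are
    never selected; ties break lexicographically by gene symbol.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > norm.n_genes:
        raise ValueError(f"k={k} exceeds the {norm.n_genes} available genes")
    means = norm.values.mean(axis=1)
    variances = norm.values.var(axis=1, ddof=1) if norm.n_cells > 1 else np.zeros(
        norm.n_genes
    )
    if method == "variance":
        score = variances
    elif method == "trend":
        order = np.argsort(means, kind="stable")
        if window is None:
            window = max(31, norm.n_genes // 20)
        window = min(window | 1, norm.n_genes)  # odd, capped
        trend_sorted = (
            pd.Series(variances[order])
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        trend = np.empty_like(trend_sorted)
        trend[order] = trend_sorted
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(trend > 0, variances / trend, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    score = np.where(variances > 0, score, -np.inf)
    ranking = sorted(
        range(norm.n_genes), key=lambda i: (-score[i], norm.genes[i])
    )
    selected = [norm.genes[i] for i in ranking if np.isfinite(score[i])]
    return selected[:k]
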