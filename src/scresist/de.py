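"""Differential expression, consensus markers and gene-set statistics.

Group comparisons use a Wilcoxon rank-sum test per gene on log-normalized
expression, with the two standard pre-test gates (fraction-expressing and
|log2FC|) applied before testing, and Benjamini-Hochberg adjustment over
the tested genes only.  Fold-changes are computed on the de-logged scale:
``log2((mean expm1(a) + eps) / (mean expm1(b) + eps))``.

The consensus rule across a panel of lines: a gene is *resistant-specific*
when it is significantly up-regulated in resistant vs sensitive cells in at
least ``min_lines`` lines and never significantly up-regulated in the
opposite direction in any line (and symmetrically for sensitive-specific).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "pseudobulk_profile",
    "pseudobulk_log2fc",
    "group_de",
    "MarkerSets",
    "consensus_markers",
    "ora_enrichment",
    "signature_score",
]

#: pseudocount protecting the fold-change ratio; arbitrary, configurable
LOG2FC_EPS = 1e-9


def pseudobulk_profile(norm: NormalizedMatrix, cells) -> pd.Series:
    """Per-gene arithmetic mean of log-normalized expression over a cell subset."""
    cells = pd.Index(cells)
    if len(cells) == 0:
        raise ValueError("pseudobulk over an empty cell subset")
    idx = norm.cell_indexer(cells)
    return pd.Series(norm.values[:, idx].mean(axis=1), index=norm.genes, name="mean")


def pseudobulk_log2fc(
    norm: NormalizedMatrix, cells_a, cells_b, eps: float = LOG2FC_EPS
) -> pd.Series:
    """Per-gene log2 fold-change of de-logged group means (A over B)."""
    ia = norm.cell_indexer(pd.Index(cells_a))
    ib = norm.cell_indexer(pd.Index(cells_b))
    mean_a = np.expm1(norm.values[:, ia]).mean(axis=1)
    mean_b = np.expm1(norm.values[:, ib]).mean(axis=1)
    return pd.Series(
        np.log2((mean_a + eps) / (mean_b + eps)), index=norm.genes, name="log2fc"
    )


def group_de(
    norm: NormalizedMatrix,
    cells_a,
    cells_b,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    eps: float = LOG2FC_EPS,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression of group A versus group B.

    Genes enter the test only when ``max(pct_a, pct_b) >= min_pct`` and
    ``|log2fc| >= logfc_threshold``; BH adjustment runs over tested genes
    only.  Returns one row per tested gene with columns ``log2fc``,
    ``pct_a``, ``pct_b``, ``p_raw``, ``p_adj`` and ``direction``
    (``up_in_a`` / ``up_in_b``).
    """
    ia = norm.cell_indexer(pd.Index(cells_a))
    ib = norm.cell_indexer(pd.Index(cells_b))
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs at least 3 cells")
    a = norm.values[:, ia]
    b = norm.values[:, ib]
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))

    testable = (np.maximum(pct_a, pct_b) >= min_pct) & (
        np.abs(log2fc) >= logfc_threshold
    )
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pct_a": pct_a,
            "pct_b": pct_b,
        },
        index=norm.genes,
    ).loc[testable]
    if result.empty:
        logger.warning("no gene passes the DE pre-test gates")
        result["p_raw"] = result["p_adj"] = np.nan
        result["direction"] = pd.Series(dtype=object)
        return result

    tested = np.flatnonzero(testable)
    # vectorized rank-sum test with normal approximation and tie correction
    p_raw = stats.mannwhitneyu(
        a[tested], b[tested], axis=1, alternative="two-sided", method="asymptotic"
    ).pvalue
    result["p_raw"] = p_raw
    result["p_adj"] = multipletests(p_raw, method="fdr_bh")[1]
    result["direction"] = np.where(result["log2fc"] > 0, "up_in_a", "up_in_b")
    return result.sort_values("p_adj", kind="stable")


@dataclass
class MarkerSets:
    """Consensus marker genes with their per-line support."""

    resistant_specific: dict[str, list[str]] = field(default_factory=dict)
    sensitive_specific: dict[str, list[str]] = field(default_factory=dict)

    @property
    def resistant_genes(self) -> list[str]:
        return sorted(self.resistant_specific)

    @property
    def sensitive_genes(self) -> list[str]:
        return sorted(self.sensitive_specific)

    @property
    def all_genes(self) -> list[str]:
        return sorted(set(self.resistant_specific) | set(self.sensitive_specific))

    def as_gene_sets(self) -> dict[str, list[str]]:
        return {
            "RESISTANT_SPECIFIC": self.resistant_genes,
            "SENSITIVE_SPECIFIC": self.sensitive_genes,
        }


def consensus_markers(
    per_line_de: dict[str, pd.DataFrame],
    min_lines: int = 2,
    alpha: float = 0.05,
) -> MarkerSets:
    """Apply the cross-line consensus rule to per-line DE tables.

    Each table must be a :func:`group_de` result computed as *resistant (A)
    versus sensitive (B)*.  Only rows with ``p_adj < alpha`` count as
    detected.  A gene is resistant-specific when detected up-in-resistant
    in at least ``min_lines`` lines and up-in-sensitive in none; the
    sensitive-specific rule is symmetric.  The output is invariant to line
    ordering.
    """
    if len(per_line_de) < min_lines:
        raise ValueError(
            f"need at least min_lines={min_lines} lines, got {len(per_line_de)}"
        )
    up_support: dict[str, set[str]] = {}
    down_support: dict[str, set[str]] = {}
    for line, table in per_line_de.items():
        significant = table[table["p_adj"] < alpha]
        for gene in significant.index[significant["direction"] == "up_in_a"]:
            up_support.setdefault(gene, set()).add(line)
        for gene in significant.index[significant["direction"] == "up_in_b"]:
            down_support.setdefault(gene, set()).add(line)
    resistant = {
        g: sorted(lines)
        for g, lines in up_support.items()
        if len(lines) >= min_lines and g not in down_support
    }
    sensitive = {
        g: sorted(lines)
        for g, lines in down_support.items()
        if len(lines) >= min_lines and g not in up_support
    }
    return MarkerSets(resistant_specific=resistant, sensitive_specific=sensitive)


def ora_enrichment(
    query, gene_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list in each set.

    ``p_raw = P(X >= k)`` for a hypergeometric draw of ``n = |query|`` genes
    from a universe of ``N`` with ``K`` set members; ``q`` is BH across all
    sets.  Sets are intersected with the universe first.
    """
    universe = pd.Index(universe).unique()
    if len(universe) == 0:
        raise ValueError("empty universe")
    query = pd.Index(query).unique()
    if not query.isin(universe).all():
        missing = query[~query.isin(universe)].tolist()
        raise ValueError(f"query genes outside the universe: {missing[:5]}")
    n = len(query)
    big_n = len(universe)
    rows = []
    for name, members in gene_sets.items():
        members_in = pd.Index(members).unique()
        members_in = members_in[members_in.isin(universe)]
        k = int(query.isin(members_in).sum())
        big_k = len(members_in)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {"set": name, "k": k, "K": big_k, "n": n, "N": big_n, "p_raw": p}
        )
    result = pd.DataFrame(rows).set_index("set")
    if len(result):
        result["q"] = multipletests(result["p_raw"], method="fdr_bh")[1]
    return result.sort_values("p_raw", kind="stable")


def signature_score(
    norm: NormalizedMatrix, gene_set, name: str = "signature"
) -> pd.Series:
    """Mean z-score signature activity per cell.

    Each set gene present in the matrix is z-scored across cells
    (zero-variance genes score 0), and the per-cell signature value is the
    mean z over set genes.
    """
    present = pd.Index(gene_set).unique()
    present = present[present.isin(norm.genes)]
    if len(present) == 0:
        raise ValueError(f"no gene of set {name!r} present in the matrix")
    sub = norm.values[norm.gene_indexer(present)]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / sd, 0.0)
    return pd.Series(z.mean(axis=0), index=norm.cells, name=name)
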