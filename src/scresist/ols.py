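"""Per-cell similarity to reference expression profiles by least squares.

Each cell's expression vector over a selected gene panel is regressed on
the sensitive and resistant pseudo-bulk profiles with an intercept:

    y_cell ~ beta0 + beta_s * x_sensitive + beta_r * x_resistant

Negative weights are clipped at zero and the similarity score is the
normalized resistant weight ``beta_r / (beta_s + beta_r)``, a bounded
[0, 1] statistic: 1 means fully resistant-like, 0 fully sensitive-like.
Sensitive cells scoring above the cut-off (default 0.5) are called
*resistant-like* — cells carrying the resistant transcriptional program
before any selective pressure.  Within-population heterogeneity is
summarized as the inter-quartile range (IQR) of the scores, and across a
line panel the IQR is correlated with drug IC50 by Spearman rank
correlation with an exact permutation p-value at small panel sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix

__all__ = [
    "OLSGeneSelection",
    "select_ols_genes",
    "ols_score_cells",
    "classify_pdr_like",
    "heterogeneity_iqr",
    "correlate_iqr_ic50",
]


@dataclass
class OLSGeneSelection:
    """Gene panel feeding the least-squares fit."""

    genes: list[str]
    log2fc: pd.Series
    fc_threshold: float
    top_k: int


def select_ols_genes(
    bulk_log2fc: pd.Series,
    variable_genes,
    fc_threshold: float = 0.5,
    top_k: int = 2000,
) -> OLSGeneSelection:
    """Intersect strong fold-change genes with the top variable genes.

    A gene qualifies when ``|log2fc| >= fc_threshold`` (inclusive) *and* it
    lies among the first ``top_k`` entries of the variable-gene ranking.
    The output preserves variable-gene rank order.
    """
    head = list(variable_genes)[:top_k]
    strong = set(bulk_log2fc.index[bulk_log2fc.abs() >= fc_threshold])
    genes = [g for g in head if g in strong]
    if not genes:
        raise ValueError(
            "no gene satisfies the fold-change/variable-gene intersection; "
            "lower fc_threshold or raise top_k"
        )
    return OLSGeneSelection(
        genes=genes,
        log2fc=bulk_log2fc.loc[genes],
        fc_threshold=fc_threshold,
        top_k=top_k,
    )


def ols_score_cells(
    norm: NormalizedMatrix,
    selection: OLSGeneSelection,
    profile_sensitive: pd.Series,
    profile_resistant: pd.Series,
    collinearity_limit: float = 0.999,
) -> pd.DataFrame:
    """Fit every cell against the two reference profiles.

    Returns one row per cell with the raw fitted weights (``beta_s_raw``,
    ``beta_r_raw``), the zero-clipped weights, the [0, 1] similarity
    ``score`` and the residual RMS.  Cells whose clipped weights are both
    zero get score 0.5 and ``degenerate=True`` so cell counts are conserved.
    """
    genes = selection.genes
    x_s = profile_sensitive.loc[genes].to_numpy(dtype=float)
    x_r = profile_resistant.loc[genes].to_numpy(dtype=float)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for the two-profile fit")
    r = np.corrcoef(x_s, x_r)[0, 1]
    if abs(r) > collinearity_limit:
        raise ValueError(
            f"reference profiles nearly collinear (|r|={abs(r):.4f} > "
            f"{collinearity_limit}); the fit cannot separate them"
        )
    design = np.column_stack([np.ones_like(x_s), x_s, x_r])
    y = norm.values[norm.gene_indexer(genes)]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residual = y - design @ beta
    rms = np.sqrt((residual**2).mean(axis=0))
    beta_s_raw, beta_r_raw = beta[1], beta[2]
    # clip negatives; weights below numerical noise snap to zero so that
    # pure-profile cells score exactly 0 or 1
    tol = 1e-12 * (np.abs(beta_s_raw) + np.abs(beta_r_raw))
    beta_s = np.where(beta_s_raw > tol, beta_s_raw, 0.0)
    beta_r = np.where(beta_r_raw > tol, beta_r_raw, 0.0)
    denom = beta_s + beta_r
    degenerate = denom == 0
    score = np.where(degenerate, 0.5, beta_r / np.where(degenerate, 1.0, denom))
    return pd.DataFrame(
        {
            "beta_s_raw": beta_s_raw,
            "beta_r_raw": beta_r_raw,
            "beta_s": beta_s,
            "beta_r": beta_r,
            "score": score,
            "residual_rms": rms,
            "degenerate": degenerate,
        },
        index=norm.cells,
    )


def classify_pdr_like(
    scores: pd.DataFrame,
    condition: pd.Series,
    cutoff: float = 0.5,
):
    """Call discordant cells and summarize per-population heterogeneity.

    Sensitive cells with ``score > cutoff`` are *resistant-like*
    (``pdr_like``); resistant cells with ``score < cutoff`` are
    *sensitive-like* (``pds_like``).  Both inequalities are strict, so a
    cell exactly at the cut-off stays unclassified (``boundary``).

    Returns ``(summary, calls)``: per-condition rows with cell count, score
    IQR and discordant fraction, plus the per-cell call series.
    """
    if scores.empty:
        raise ValueError("no scores to classify")
    condition = condition.reindex(scores.index)
    if condition.isna().any():
        raise ValueError("condition missing for some scored cells")
    s = scores["score"]
    calls = pd.Series("concordant", index=scores.index, name="call", dtype=object)
    calls[(condition == "sensitive") & (s > cutoff)] = "pdr_like"
    calls[(condition == "resistant") & (s < cutoff)] = "pds_like"
    calls[s == cutoff] = "boundary"
    rows = []
    for cond, idx in s.groupby(condition).groups.items():
        sub = s.loc[idx]
        discordant = "pdr_like" if cond == "sensitive" else "pds_like"
        rows.append(
            {
                "condition": cond,
                "n_cells": len(sub),
                "iqr": heterogeneity_iqr(sub) if len(sub) >= 4 else np.nan,
                "discordant_fraction": float((calls.loc[idx] == discordant).mean()),
            }
        )
    summary = pd.DataFrame(rows).set_index("condition")
    return summary, calls


def heterogeneity_iqr(scores) -> float:
    """Inter-quartile range with linear-interpolation quantiles."""
    values = np.asarray(scores, dtype=float)
    if values.size < 4:
        raise ValueError("IQR needs at least 4 scores")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    return float(q3 - q1)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (Pearson on ranks)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho_perm = (ry_c @ rx_c) / denom
    return float((np.abs(rho_perm) >= abs(rho_obs) - 1e-12).mean())


def correlate_iqr_ic50(
    iqr_by_line: dict[str, float],
    ic50_by_line: dict[str, float],
    exact_max_n: int = 9,
):
    """Spearman correlation of per-line score IQR with IC50.

    Uses an exact two-sided permutation p-value (all ``n!`` assignments)
    for panels of up to ``exact_max_n`` lines, and the asymptotic
    approximation beyond.  Returns ``(rho, p, n_lines)``.
    """
    shared = sorted(set(iqr_by_line) & set(ic50_by_line))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared lines, got {len(shared)}")
    x = np.array([iqr_by_line[k] for k in shared], dtype=float)
    y = np.array([ic50_by_line[k] for k in shared], dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(shared)
    if n <= exact_max_n and math.factorial(n) <= 500_000:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p, n
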