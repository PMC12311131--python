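"""End-to-end orchestration of the per-line and panel analyses.

``analyze_line`` runs the full single-line chain: expressed-gene
detection, cell QC, log-normalization, variable-gene selection,
resistant-vs-sensitive differential expression, OLS gene selection,
per-cell similarity scoring, resistant-like calls and the score IQR.
``analyze_panel`` maps it over a multi-line panel, derives consensus
markers and correlates per-line sensitive-population IQR with IC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .containers import CountMatrix, NormalizedMatrix
from .de import MarkerSets, consensus_markers, group_de, pseudobulk_log2fc, pseudobulk_profile
from .ols import (
    OLSGeneSelection,
    classify_pdr_like,
    correlate_iqr_ic50,
    select_ols_genes,
)
from .ols import ols_score_cells
from .qc import detect_expressed_genes, filter_cells, lognormalize, top_variable_genes

__all__ = ["LineResult", "PanelResult", "analyze_line", "analyze_panel"]


@dataclass
class LineResult:
    """All artifacts of one line's sensitive/resistant analysis."""

    line_id: str
    qc_report: pd.DataFrame
    norm: NormalizedMatrix
    annotation: pd.DataFrame
    variable_genes: list[str]
    de: pd.DataFrame  # resistant (A) vs sensitive (B)
    selection: OLSGeneSelection
    scores: pd.DataFrame
    summary: pd.DataFrame
    calls: pd.Series

    @property
    def iqr_sensitive(self) -> float:
        return float(self.summary.loc["sensitive", "iqr"])

    @property
    def pdr_like_fraction(self) -> float:
        return float(self.summary.loc["sensitive", "discordant_fraction"])


@dataclass
class PanelResult:
    """Panel-level outputs over all lines."""

    lines: dict[str, LineResult]
    markers: MarkerSets
    iqr_by_line: dict[str, float]
    rho: float | None = None
    p: float | None = None
    ic50_by_line: dict[str, float] = field(default_factory=dict)


def analyze_line(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    config: RunConfig | None = None,
    line_id: str | None = None,
) -> LineResult:
    """Run the complete per-line analysis on one paired dataset."""
    config = config or RunConfig()
    line_id = line_id or str(annotation.get("line", pd.Series(["line"])).iloc[0])
    expressed = detect_expressed_genes(
        counts, config.rel_expr_threshold, config.min_cells_expressed
    )
    filtered, qc_report = filter_cells(
        counts, expressed, config.min_genes, config.max_genes, config.max_mito
    )
    norm = lognormalize(filtered, scale=config.lognorm_scale)
    annotation = annotation.reindex(norm.cells)
    variable = top_variable_genes(norm, k=min(config.top_k_variable, norm.n_genes))
    sens = norm.cells[annotation["condition"] == "sensitive"]
    res = norm.cells[annotation["condition"] == "resistant"]
    de = group_de(
        norm, res, sens,
        min_pct=config.de_min_pct,
        logfc_threshold=config.de_logfc_threshold,
    )
    bulk_fc = pseudobulk_log2fc(norm, res, sens)
    selection = select_ols_genes(
        bulk_fc.loc[variable], variable,
        fc_threshold=config.ols_fc_threshold,
        top_k=config.top_k_variable,
    )
    profile_s = pseudobulk_profile(norm, sens)
    profile_r = pseudobulk_profile(norm, res)
    scores = ols_score_cells(norm, selection, profile_s, profile_r)
    summary, calls = classify_pdr_like(
        scores, annotation["condition"], cutoff=config.ols_cutoff
    )
    return LineResult(
        line_id=line_id,
        qc_report=qc_report,
        norm=norm,
        annotation=annotation,
        variable_genes=variable,
        de=de,
        selection=selection,
        scores=scores,
        summary=summary,
        calls=calls,
    )


def analyze_panel(
    datasets: dict[str, tuple],
    ic50_by_line: dict[str, float] | None = None,
    config: RunConfig | None = None,
) -> PanelResult:
    """Analyze every line of a panel and the cross-line statistics.

    ``datasets`` maps line id to ``(CountMatrix, annotation, ...)`` tuples
    (any extra tuple members, e.g. ground truth, are ignored).
    """
    config = config or RunConfig()
    lines = {
        line_id: analyze_line(data[0], data[1], config, line_id=line_id)
        for line_id, data in datasets.items()
    }
    markers = consensus_markers(
        {lid: r.de for lid, r in lines.items()},
        min_lines=config.consensus_min_lines,
        alpha=config.de_alpha,
    )
    iqr_by_line = {lid: r.iqr_sensitive for lid, r in lines.items()}
    result = PanelResult(lines=lines, markers=markers, iqr_by_line=iqr_by_line)
    if ic50_by_line:
        result.ic50_by_line = dict(ic50_by_line)
        result.rho, result.p, _ = correlate_iqr_ic50(iqr_by_line, result.ic50_by_line)
    return result
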