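"""Run configuration: every tunable of the pipeline in one record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their default values.

    QC
    ----
    min_genes, max_genes : int
        Retain cells with between 2000 and 7000 expressed genes (inclusive).
    max_mito : float
        Maximum fraction of counts mapping to mitochondrial genes (0.10).
    rel_expr_threshold, min_cells_expressed
        A gene counts as expressed when its size-factor-scaled count is at
        least 0.1 in at least 10 cells.
    top_k_variable : int
        Number of top variable genes retained for downstream gene selection.

    Similarity scoring
    ------------------
    ols_fc_threshold : float
        Minimum pseudo-bulk |log2FC| for a gene to enter the OLS gene set.
    ols_cutoff : float
        Score cut-off above which a sensitive cell is called resistant-like.

    Differential expression
    -----------------------
    de_min_pct, de_logfc_threshold
        Pre-test gates on fraction-expressing and |log2FC|.
    de_alpha : float
        BH-adjusted significance gate feeding the consensus-marker rule.
    consensus_min_lines : int
        Minimum supporting lines for a consensus marker.

    Cohort heterogeneity
    --------------------
    cohort_min_genes : int
        Minimum detected genes per cohort cell (500).
    cohort_de_min_pct, cohort_de_logfc_threshold
        Baseline DE gates (the defaults of a standard marker test).
    dist_n_cells, dist_n_random
        Cells sampled and random gene sets drawn by the distance statistic.
    """

    # QC / normalization
    min_genes: int = 2000
    max_genes: int = 7000
    max_mito: float = 0.10
    rel_expr_threshold: float = 0.1
    min_cells_expressed: int = 10
    top_k_variable: int = 2000
    lognorm_scale: float = 1e4
    # OLS similarity
    ols_fc_threshold: float = 0.5
    ols_cutoff: float = 0.5
    # differential expression / markers
    de_min_pct: float = 0.25
    de_logfc_threshold: float = 0.25
    de_alpha: float = 0.05
    consensus_min_lines: int = 2
    # clustering
    n_pcs: int = 20
    k_neighbors: int = 20
    cluster_resolution: float = 0.6
    # cohort
    cohort_min_genes: int = 500
    cohort_de_min_pct: float = 0.1
    cohort_de_logfc_threshold: float = 0.25
    dist_n_cells: int = 1000
    dist_n_random: int = 100
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito <= 1:
            raise ValueError("max_mito must be a proportion in [0, 1]")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")
        for name in ("de_min_pct", "cohort_de_min_pct", "ols_cutoff", "de_alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "min_cells_expressed",
            "top_k_variable",
            "consensus_min_lines",
            "dist_n_cells",
            "dist_n_random",
            "n_pcs",
            "k_neighbors",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat ``key = value`` or ``key: value`` file."""
        values: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            sep = "=" if "=" in line else ":"
            if sep not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split(sep, 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            values[key] = type(default)(float(value)) if not isinstance(
                default, str
            ) else value
        return cls(**values)

    def with_overrides(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in overrides.items() if v is not None})
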