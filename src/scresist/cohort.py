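"""Cohort-level heterogeneity analysis (patients x timepoints).

Mirrors the clinical-cohort arm of the pipeline: light per-cell QC,
baseline (day 0) differential expression between sensitive and resistant
patients, per-cell OLS similarity against the two baseline arm
pseudo-bulks, a proportion test for marker enrichment among DE genes, and
the distance-based heterogeneity statistic — the average pairwise
euclidean distance among sampled cells on the marker genes, referenced
against a null of size-matched random gene sets drawn from the top
variable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .containers import CountMatrix, NormalizedMatrix
from .de import group_de
from .ols import OLSGeneSelection, ols_score_cells

logger = logging.getLogger(__name__)

__all__ = [
    "cohort_qc",
    "baseline_de",
    "cohort_ols",
    "marker_proportion_test",
    "ProportionTestResult",
    "distance_heterogeneity",
    "DistanceHeterogeneity",
]


def cohort_qc(
    counts: CountMatrix,
    min_genes: int = 500,
    annotation: pd.DataFrame | None = None,
) -> CountMatrix:
    """Retain cells with at least ``min_genes`` detected genes (inclusive).

    Detection here means a nonzero count on any gene — the lighter rule
    appropriate for shallow clinical droplet data.  If an annotation with a
    ``patient`` column is given, patients losing every cell are warned about.
    """
    detected = (counts.counts > 0).sum(axis=0)
    keep = detected >= min_genes
    if annotation is not None and "patient" in annotation:
        patients = annotation.reindex(counts.cells)["patient"]
        for patient in patients.unique():
            mask = (patients == patient).to_numpy()
            if mask.any() and not keep[mask].any():
                logger.warning("patient %s loses all cells at QC", patient)
    return counts.subset_cells(counts.cells[keep])


def baseline_de(
    norm: NormalizedMatrix,
    cells_sensitive_d0,
    cells_resistant_d0,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Resistant-vs-sensitive DE restricted to baseline (day 0) cells.

    Group A is the resistant arm, so ``up_in_a`` marks genes higher in
    resistant patients.  Gates default to the standard marker-test
    defaults (``min_pct=0.1``, ``logfc_threshold=0.25``).
    """
    return group_de(
        norm,
        cells_resistant_d0,
        cells_sensitive_d0,
        min_pct=min_pct,
        logfc_threshold=logfc_threshold,
    )


def cohort_ols(
    norm: NormalizedMatrix,
    de_table: pd.DataFrame,
    annotation: pd.DataFrame,
    baseline_timepoint: str = "D0",
):
    """Score every cohort cell against the baseline arm pseudo-bulks.

    Reference profiles are the day-0 pseudo-bulk of each arm; the gene
    panel is the baseline DE gene list.  Besides the bounded [0, 1]
    resistance ``score`` (clipped-weight ratio), each cell gets an
    *own-arm similarity*: ``1 - |w_own - 1|`` where ``w_own`` is the raw
    (unclipped) mixture-weight fraction of the cell's own arm profile.  A
    cell sitting exactly on its arm's pseudo-bulk scores 1; deviation
    along the resistance axis in either direction lowers it, so a more
    heterogeneous arm shows stochastically lower similarity.  (The
    bounded score cannot express this: cells beyond their own profile
    clip to an atom at 0 or 1, which cancels the inward tail in a rank
    test.)  Returns ``(scores, summary, tests)`` where ``tests`` holds,
    per timepoint, the two-sided Wilcoxon p comparing own-arm similarity
    between resistant and sensitive cells.
    """
    annotation = annotation.reindex(norm.cells)
    if set(annotation["condition"].dropna().unique()) != {"sensitive", "resistant"}:
        raise ValueError("cohort needs both a sensitive and a resistant arm")
    genes = [g for g in de_table.index if g in norm.genes]
    if len(genes) < 3:
        raise ValueError("fewer than 3 baseline DE genes present in the matrix")
    at_d0 = annotation["timepoint"] == baseline_timepoint
    d0_sens = norm.cells[(annotation["condition"] == "sensitive") & at_d0]
    d0_res = norm.cells[(annotation["condition"] == "resistant") & at_d0]
    if len(d0_sens) == 0 or len(d0_res) == 0:
        raise ValueError("both arms must have baseline cells")
    gene_idx = norm.gene_indexer(genes)
    profile_s = pd.Series(
        norm.values[np.ix_(gene_idx, norm.cell_indexer(d0_sens))].mean(axis=1),
        index=genes,
    )
    profile_r = pd.Series(
        norm.values[np.ix_(gene_idx, norm.cell_indexer(d0_res))].mean(axis=1),
        index=genes,
    )
    selection = OLSGeneSelection(
        genes=genes,
        log2fc=de_table.loc[genes, "log2fc"],
        fc_threshold=0.0,
        top_k=len(genes),
    )
    scores = ols_score_cells(norm, selection, profile_s, profile_r)
    scores["condition"] = annotation["condition"]
    scores["timepoint"] = annotation["timepoint"]
    denom = scores["beta_s_raw"] + scores["beta_r_raw"]
    raw_fraction = np.where(
        np.abs(denom) > 1e-12, scores["beta_r_raw"] / denom.where(denom != 0, 1.0), 0.5
    )
    own_weight = np.where(
        scores["condition"] == "resistant", raw_fraction, 1 - raw_fraction
    )
    scores["own_arm_similarity"] = 1 - np.abs(own_weight - 1)
    summary = (
        scores.groupby(["condition", "timepoint"], observed=True)["own_arm_similarity"]
        .agg(["count", "median", "mean"])
        .rename(columns={"count": "n_cells"})
    )
    tests = {}
    for tp, sub in scores.groupby("timepoint", observed=True):
        res = sub.loc[sub["condition"] == "resistant", "own_arm_similarity"]
        sens = sub.loc[sub["condition"] == "sensitive", "own_arm_similarity"]
        if len(res) and len(sens):
            tests[tp] = float(
                stats.mannwhitneyu(res, sens, alternative="two-sided").pvalue
            )
    return scores, summary, tests


@dataclass
class ProportionTestResult:
    """Two-sample test of marker proportion among DE genes vs the universe."""

    k_de_markers: int
    n_de: int
    k_universe_markers: int
    n_universe: int
    statistic: float  # chi-square (squared z) after continuity correction
    p: float  # one-sided, greater marker fraction among DE genes


def marker_proportion_test(
    de_genes, marker_genes, universe
) -> ProportionTestResult:
    """Are markers over-represented among DE genes relative to the universe?

    Two-sample proportion z-test with continuity correction (the correction
    is capped at the observed difference so equal proportions give a zero
    statistic), one-sided in the direction of a *greater* marker fraction
    among the DE genes.
    """
    universe = pd.Index(universe).unique()
    de = pd.Index(de_genes).unique()
    if len(de) == 0:
        raise ValueError("empty DE gene list")
    markers = pd.Index(marker_genes).unique()
    markers = markers[markers.isin(universe)]
    k1, n1 = int(de.isin(markers).sum()), len(de)
    k2, n2 = len(markers), len(universe)
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    correction = min(0.5 * (1 / n1 + 1 / n2), abs(p1 - p2))
    if se == 0:
        z = 0.0
    else:
        z = (p1 - p2 - np.sign(p1 - p2) * correction) / se
    return ProportionTestResult(
        k_de_markers=k1,
        n_de=n1,
        k_universe_markers=k2,
        n_universe=n2,
        statistic=float(z**2),
        p=float(stats.norm.sf(z)),
    )


@dataclass
class DistanceHeterogeneity:
    """Average pairwise distance on markers against a random-gene-set null."""

    group_id: str
    marker_distance: float
    null_distances: np.ndarray
    n_cells_sampled: int
    n_random: int
    gene_set_size: int
    seed: int

    @property
    def null_quantile(self) -> float:
        """Empirical quantile of the marker distance within the null."""
        return float((self.null_distances <= self.marker_distance).mean())


def _mean_pairwise_distance(values: np.ndarray) -> float:
    """Mean euclidean distance over all unordered cell pairs (cells x genes)."""
    return float(pdist(values, metric="euclidean").mean())


def distance_heterogeneity(
    norm: NormalizedMatrix,
    marker_genes,
    top_variable,
    group_cells,
    group_id: str = "group",
    n_cells: int = 1000,
    n_random: int = 100,
    seed: int = 0,
) -> DistanceHeterogeneity:
    """Marker-gene distance heterogeneity of one cell group vs a null.

    Samples ``n_cells`` cells without replacement (all cells with a warning
    when the group is smaller), computes the average pairwise euclidean
    distance on the marker genes, and repeats the same statistic on the
    *same* sampled cells for ``n_random`` random draws of
    ``len(marker_genes)`` genes from the top variable genes excluding the
    markers.  Cell and gene order do not affect the result for a given seed.
    """
    markers = sorted(pd.Index(marker_genes).unique())
    top = pd.Index(top_variable).unique()
    if not pd.Index(markers).isin(top).all():
        raise ValueError("marker_genes must be a subset of top_variable")
    pool = sorted(top[~top.isin(markers)])
    if len(pool) < len(markers):
        raise ValueError(
            f"only {len(pool)} non-marker variable genes available for "
            f"null draws of size {len(markers)}"
        )
    cells = sorted(pd.Index(group_cells).unique())
    rng = np.random.default_rng(seed)
    if len(cells) > n_cells:
        sampled = list(rng.choice(cells, size=n_cells, replace=False))
    else:
        if len(cells) < n_cells:
            logger.warning(
                "group %s has %d cells (< %d): using all", group_id, len(cells), n_cells
            )
        sampled = cells
    cell_idx = norm.cell_indexer(sampled)
    marker_values = norm.values[np.ix_(norm.gene_indexer(markers), cell_idx)].T
    marker_distance = _mean_pairwise_distance(marker_values)
    null = np.empty(n_random)
    for j in range(n_random):
        draw = rng.choice(pool, size=len(markers), replace=False)
        vals = norm.values[np.ix_(norm.gene_indexer(sorted(draw)), cell_idx)].T
        null[j] = _mean_pairwise_distance(vals)
    return DistanceHeterogeneity(
        group_id=group_id,
        marker_distance=marker_distance,
        null_distances=null,
        n_cells_sampled=len(sampled),
        n_random=n_random,
        gene_set_size=len(markers),
        seed=seed,
    )
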