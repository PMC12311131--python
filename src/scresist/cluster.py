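"""Transcriptional sub-clustering of resistant populations.

Cells are clustered by Louvain community detection on a shared-nearest-
neighbor (SNN) graph built in principal-component space, using the top
variable genes restricted to the genes differentially expressed between
resistant and sensitive cells — i.e. the axis of variation relevant to the
resistance program.  Clusters are then characterized by one-vs-rest
differential expression, gene-set over-representation of their
up-regulated genes, and mean signature scores.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import NormalizedMatrix
from .de import group_de, ora_enrichment, signature_score

logger = logging.getLogger(__name__)

__all__ = [
    "clustering_gene_space",
    "louvain_cluster",
    "ClusterAssignment",
    "characterize_clusters",
    "ClusterCharacterization",
]


def clustering_gene_space(variable_genes, de_genes) -> list[str]:
    """Variable genes restricted to DE genes, in variable-gene rank order."""
    variable_genes = list(variable_genes)
    de = set(de_genes)
    if not variable_genes or not de:
        raise ValueError("both gene lists must be nonempty")
    genes = [g for g in variable_genes if g in de]
    if not genes:
        raise ValueError("variable genes and DE genes do not intersect")
    return genes


@dataclass
class ClusterAssignment:
    """Louvain community labels (contiguous from 0, ordered by size)."""

    labels: pd.Series
    resolution: float
    genes: list[str]
    n_pcs: int
    k_neighbors: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _snn_graph(pcs: np.ndarray, k: int, prune: float = 1 / 15) -> igraph.Graph:
    """Jaccard-weighted shared-nearest-neighbor graph (self included in
    each neighbor set, as is conventional)."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    adj = scipy.sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()
    jaccard = shared.data / (2 * k - shared.data)
    mask = (shared.row < shared.col) & (jaccard >= prune)
    edges = list(zip(shared.row[mask].tolist(), shared.col[mask].tolist()))
    graph = igraph.Graph(n=n, edges=edges)
    graph.es["weight"] = jaccard[mask].tolist()
    return graph


def louvain_cluster(
    norm: NormalizedMatrix,
    genes,
    n_pcs: int = 20,
    k_neighbors: int = 20,
    resolution: float = 0.6,
    seed: int = 0,
) -> ClusterAssignment:
    """PCA -> SNN graph -> Louvain modularity communities.

    Genes are z-scored across cells before PCA.  Community labels are
    relabeled by descending cluster size so label 0 is always the largest
    cluster; the same seed yields identical labels.
    """
    genes = list(genes)
    if norm.n_cells < 2 * k_neighbors:
        raise ValueError(
            f"need at least {2 * k_neighbors} cells for k_neighbors={k_neighbors}"
        )
    sub = norm.values[norm.gene_indexer(genes)].T  # cells x genes
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n_comp = min(n_pcs, z.shape[0] - 1, z.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z)
    graph = _snn_graph(pcs, k=min(k_neighbors, norm.n_cells - 1))
    random.seed(seed)  # igraph draws from Python's RNG
    communities = graph.community_multilevel(
        weights="weight", resolution=resolution
    )
    raw = np.asarray(communities.membership)
    # relabel by descending size, ties by original label
    order = sorted(
        np.unique(raw), key=lambda c: (-(raw == c).sum(), c)
    )
    relabel = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[c] for c in raw], index=norm.cells, name="cluster"
    )
    return ClusterAssignment(
        labels=labels,
        resolution=resolution,
        genes=genes,
        n_pcs=n_comp,
        k_neighbors=k_neighbors,
        seed=seed,
    )


@dataclass
class ClusterCharacterization:
    """Per-cluster DE, enrichment and signature summaries."""

    de: dict[int, pd.DataFrame] = field(default_factory=dict)
    enrichment: dict[int, pd.DataFrame] = field(default_factory=dict)
    signature_means: pd.DataFrame | None = None
    marker_table: pd.DataFrame | None = None


def characterize_clusters(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    gene_sets: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    top_markers: int = 10,
) -> ClusterCharacterization:
    """One-vs-rest DE per cluster, ORA of up-genes, mean signature scores.

    Clusters of fewer than 3 cells are skipped with a warning.  The ORA
    universe is the set of genes tested in that cluster's DE.  The marker
    table reports mean expression of each cluster's top up-regulated genes
    across all clusters (heatmap-style summary).
    """
    labels = assignment.labels
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("characterization needs at least 2 clusters")
    out = ClusterCharacterization()
    top_genes: dict[int, list[str]] = {}
    for c in clusters:
        in_c = labels.index[labels == c]
        rest = labels.index[labels != c]
        if len(in_c) < 3:
            logger.warning("cluster %d has %d cells (<3): skipped", c, len(in_c))
            continue
        table = group_de(
            norm, in_c, rest, min_pct=min_pct, logfc_threshold=logfc_threshold
        )
        out.de[c] = table
        up = table.index[
            (table["direction"] == "up_in_a") & (table["p_adj"] < alpha)
        ].tolist()
        top_genes[c] = up[:top_markers]
        if gene_sets and up:
            out.enrichment[c] = ora_enrichment(
                up, gene_sets, universe=table.index.tolist()
            )
    if gene_sets:
        sig = {
            name: signature_score(norm, members, name=name)
            for name, members in gene_sets.items()
        }
        sig_frame = pd.DataFrame(sig)
        out.signature_means = sig_frame.groupby(labels).mean()
        out.signature_means.index.name = "cluster"
    all_markers = list(dict.fromkeys(g for genes in top_genes.values() for g in genes))
    if all_markers:
        expr = pd.DataFrame(
            norm.values[norm.gene_indexer(all_markers)],
            index=pd.Index(all_markers, name="gene"),
            columns=norm.cells,
        )
        out.marker_table = expr.T.groupby(labels).mean().T
    return out
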