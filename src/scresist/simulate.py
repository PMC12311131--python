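"""Synthetic single-cell data with known ground truth.

The generator emulates the layout of a drug-resistance single-cell study:
cell-line panels in which each line contributes a drug-sensitive parental
population and a resistant derivative, and a clinical-style cohort of
patients sampled at several timepoints.

The mechanism is deliberately minimal: every resistance-related statistic
downstream is driven by a single per-cell *program activation* scalar
``a_i in [0, 1]``.

* Resistant cells draw ``a_i ~ Normal(1, program_heterogeneity)`` clipped
  to ``[0, 1]``.
* Sensitive cells sit at ``a_i = 0``, except for a planted
  ``pdr_like_fraction`` of cells that draw from the resistant distribution
  (the pre-existing resistant-like subpopulation), and an optional
  half-normal background spread ``sensitive_program_sd`` that makes the
  sensitive population continuously heterogeneous for the program.

Expected expression is ``lambda_gi = s_i * mu_g * 2**(+effect * a_i)`` on
planted up-markers, ``2**(-effect * a_i)`` on down-markers and ``s_i * mu_g``
elsewhere, with ``mu_g`` log-normal baseline means, ``s_i`` a log-normal
per-cell library factor, and counts drawn negative-binomially
(gamma-Poisson) with inverse-dispersion ``nb_dispersion``.  A block of
genes named ``MT-*`` carries a target share of each library so that
mitochondrial-fraction QC is exercised; ``RPL*`` genes provide a ribosomal
block.  Transcriptional substructure inside the resistant population is
planted as disjoint per-cluster marker subsets switched on only in that
cluster's cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix, flag_genes

__all__ = [
    "SimLineSpec",
    "SimCohortSpec",
    "GroundTruth",
    "simulate_line",
    "simulate_panel",
    "simulate_cohort",
]


@dataclass
class SimLineSpec:
    """Parameters of one simulated cell line (paired sensitive/resistant)."""

    line_id: str = "LINE1"
    n_cells_sensitive: int = 500
    n_cells_resistant: int = 500
    n_genes: int = 1000
    n_markers_up: int = 50
    n_markers_down: int = 50
    effect_log2fc: float = 2.0
    pdr_like_fraction: float = 0.03
    program_heterogeneity: float = 0.25
    sensitive_program_sd: float = 0.0
    marker_baseline_logmean: float = 1.5
    marker_baseline_sd: float = 0.5
    nb_dispersion: float = 5.0
    libsize_lognorm_sd: float = 0.3
    mito_mean_fraction: float = 0.05
    mito_cell_sd: float = 0.4
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    ic50: float = 100.0
    n_clusters: int = 1
    n_cluster_markers: int = 30
    cluster_effect_log2fc: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_cells_sensitive + self.n_cells_resistant, self.n_genes) <= 0:
            raise ValueError("spec must have at least one cell and one gene")
        reserved = (
            self.n_markers_up
            + self.n_markers_down
            + self.n_mito_genes
            + self.n_ribo_genes
            + max(self.n_clusters - 1, 0) * 0
            + (self.n_clusters * self.n_cluster_markers if self.n_clusters > 1 else 0)
        )
        if reserved >= self.n_genes:
            raise ValueError("marker/mito/ribo blocks must leave background genes")
        for name in ("pdr_like_fraction", "mito_mean_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.nb_dispersion <= 0 or self.ic50 <= 0:
            raise ValueError("nb_dispersion and ic50 must be positive")


@dataclass
class SimCohortSpec:
    """Parameters of a simulated patient cohort (two response arms)."""

    n_patients_sensitive: int = 4
    n_patients_resistant: int = 4
    cells_per_patient_per_timepoint: int = 100
    timepoints: tuple[str, ...] = ("D0", "D14", "D180")
    patient_effect_sd: float = 0.15
    resistant_extra_heterogeneity: float = 1.0
    n_genes: int = 1000
    n_markers_up: int = 50
    n_markers_down: int = 50
    effect_log2fc: float = 2.0
    program_heterogeneity: float = 0.25
    marker_baseline_logmean: float = 1.5
    marker_baseline_sd: float = 0.5
    nb_dispersion: float = 5.0
    libsize_lognorm_sd: float = 0.3
    mito_mean_fraction: float = 0.05
    n_mito_genes: int = 10
    n_ribo_genes: int = 20

    def __post_init__(self) -> None:
        if min(self.n_patients_sensitive, self.n_patients_resistant) < 2:
            raise ValueError("need at least 2 patients per arm")
        if self.resistant_extra_heterogeneity < 1:
            raise ValueError("resistant_extra_heterogeneity must be >= 1")
        if self.cells_per_patient_per_timepoint <= 0 or self.n_genes <= 0:
            raise ValueError("cells and genes must be positive")
        reserved = (
            self.n_markers_up + self.n_markers_down + self.n_mito_genes + self.n_ribo_genes
        )
        if reserved >= self.n_genes:
            raise ValueError("marker/mito/ribo blocks must leave background genes")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    marker_up_ids: list[str]
    marker_down_ids: list[str]
    program_activation: pd.Series
    true_label: pd.Series  # baseline / pdr_like / resistant
    cluster_labels: pd.Series | None = None  # resistant cells only
    cluster_marker_ids: dict[int, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _gene_panel(n_genes, n_up, n_down, n_mito, n_ribo, cluster_markers):
    """Assemble the named gene panel; background fills the remainder."""
    names = [f"RESUP{i+1}" for i in range(n_up)]
    names += [f"RESDN{i+1}" for i in range(n_down)]
    cluster_ids: dict[int, list[str]] = {}
    for c, k in cluster_markers.items():
        cluster_ids[c] = [f"CLM{c+1}N{i+1}" for i in range(k)]
        names += cluster_ids[c]
    names += [f"MT-S{i+1}" for i in range(n_mito)]
    names += [f"RPL{i+1}" for i in range(n_ribo)]
    n_background = n_genes - len(names)
    names += [f"G{i+1:05d}" for i in range(n_background)]
    return pd.Index(names, name="gene"), cluster_ids


def _baseline_means(
    rng,
    genes: pd.Index,
    mito_mean_fraction: float,
    marker_logmean: float = 0.0,
    marker_sd: float = 1.0,
) -> np.ndarray:
    """Log-normal baseline means; mito block rescaled to its target share.

    Planted marker genes draw from their own (typically better-expressed)
    stratum: resistance markers are by construction genes detectable in a
    sizeable cell fraction, not tail-of-distribution transcripts.
    """
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    is_marker = np.array(
        [g.startswith(("RESUP", "RESDN", "CLM")) for g in genes]
    )
    if is_marker.any():
        mu[is_marker] = rng.lognormal(
            mean=marker_logmean, sigma=marker_sd, size=int(is_marker.sum())
        )
    flags = flag_genes(genes)
    is_mito = flags["is_mito"].to_numpy()
    if is_mito.any() and 0 < mito_mean_fraction < 1:
        s_mito = mu[is_mito].sum()
        s_other = mu[~is_mito].sum()
        mu[is_mito] *= mito_mean_fraction * s_other / ((1 - mito_mean_fraction) * s_mito)
    return mu


def _clipped_normal(rng, loc, scale, size):
    if np.all(np.asarray(scale) == 0):
        return np.full(size, float(loc)).clip(0.0, 1.0)
    return np.clip(rng.normal(loc, scale, size=size), 0.0, 1.0)


def _nb_counts(rng, lam: np.ndarray, inverse_dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + mu^2 / inverse_dispersion."""
    shape = inverse_dispersion
    gamma = rng.gamma(shape, lam / shape)
    return rng.poisson(gamma)


def _expression_means(
    mu: np.ndarray,
    genes: pd.Index,
    activation: np.ndarray,
    effect_log2fc: float,
    up_ids,
    down_ids,
    libsize: np.ndarray,
    mito_scale: np.ndarray | None = None,
) -> np.ndarray:
    """lambda_gi for every gene and cell (genes x cells)."""
    lam = np.outer(mu, libsize)
    up_idx = genes.get_indexer(up_ids)
    down_idx = genes.get_indexer(down_ids)
    lam[up_idx] *= 2.0 ** (effect_log2fc * activation)[None, :]
    lam[down_idx] *= 2.0 ** (-effect_log2fc * activation)[None, :]
    if mito_scale is not None:
        is_mito = flag_genes(genes)["is_mito"].to_numpy()
        lam[is_mito] *= mito_scale[None, :]
    return lam


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_line(spec: SimLineSpec, seed: int):
    """Simulate one paired sensitive/resistant cell line.

    Returns ``(CountMatrix, annotation, GroundTruth)`` where the annotation
    is a per-cell DataFrame (line, condition) indexed by barcode.
    """
    rng = np.random.default_rng(seed)
    cluster_markers = (
        {c: spec.n_cluster_markers for c in range(spec.n_clusters)}
        if spec.n_clusters > 1
        else {}
    )
    genes, cluster_ids = _gene_panel(
        spec.n_genes,
        spec.n_markers_up,
        spec.n_markers_down,
        spec.n_mito_genes,
        spec.n_ribo_genes,
        cluster_markers,
    )
    up_ids = [g for g in genes if g.startswith("RESUP")]
    down_ids = [g for g in genes if g.startswith("RESDN")]
    mu = _baseline_means(
        rng, genes, spec.mito_mean_fraction,
        spec.marker_baseline_logmean, spec.marker_baseline_sd,
    )

    n_s, n_r = spec.n_cells_sensitive, spec.n_cells_resistant
    n = n_s + n_r
    barcodes = pd.Index(
        [f"{spec.line_id}-S{i+1:05d}" for i in range(n_s)]
        + [f"{spec.line_id}-R{i+1:05d}" for i in range(n_r)],
        name="barcode",
    )
    condition = np.array(["sensitive"] * n_s + ["resistant"] * n_r)

    # program activation
    activation = np.zeros(n)
    label = np.array(["baseline"] * n, dtype=object)
    if spec.sensitive_program_sd > 0:
        activation[:n_s] = _clipped_normal(rng, 0.0, spec.sensitive_program_sd, n_s)
    pdr_like = rng.random(n_s) < spec.pdr_like_fraction
    activation[:n_s][pdr_like] = _clipped_normal(
        rng, 1.0, spec.program_heterogeneity, int(pdr_like.sum())
    )
    label[:n_s][pdr_like] = "pdr_like"
    activation[n_s:] = _clipped_normal(rng, 1.0, spec.program_heterogeneity, n_r)
    label[n_s:] = "resistant"

    libsize = rng.lognormal(0.0, spec.libsize_lognorm_sd, size=n)
    mito_scale = (
        rng.lognormal(0.0, spec.mito_cell_sd, size=n) if spec.mito_cell_sd > 0 else None
    )
    lam = _expression_means(
        mu, genes, activation, spec.effect_log2fc, up_ids, down_ids, libsize, mito_scale
    )

    # per-cluster programs inside the resistant population
    cluster_series = None
    if cluster_markers:
        assignments = rng.integers(0, spec.n_clusters, size=n_r)
        for c, ids in cluster_ids.items():
            idx = genes.get_indexer(ids)
            on = np.zeros(n)
            on[n_s:] = (assignments == c).astype(float)
            lam[idx] *= 2.0 ** (spec.cluster_effect_log2fc * on)[None, :]
        cluster_series = pd.Series(assignments, index=barcodes[n_s:], name="true_cluster")

    counts = _nb_counts(rng, lam, spec.nb_dispersion)
    matrix = CountMatrix(genes, barcodes, counts)
    annotation = pd.DataFrame(
        {"line": spec.line_id, "condition": condition}, index=barcodes
    )
    truth = GroundTruth(
        marker_up_ids=up_ids,
        marker_down_ids=down_ids,
        program_activation=pd.Series(activation, index=barcodes, name="activation"),
        true_label=pd.Series(label, index=barcodes, name="true_label"),
        cluster_labels=cluster_series,
        cluster_marker_ids=cluster_ids,
    )
    return matrix, annotation, truth


def simulate_panel(
    specs: list[SimLineSpec],
    iqr_ic50_rho: float = 1.0,
    seed: int = 0,
    heterogeneity_range: tuple[float, float] = (0.05, 0.5),
):
    """Simulate a multi-line panel with a controlled heterogeneity-IC50 link.

    With ``iqr_ic50_rho > 0`` the sensitive-population program spread
    (``sensitive_program_sd``) is assigned monotone-increasing in IC50, so
    the planted Spearman correlation between sensitive heterogeneity and
    IC50 is exactly 1.  With ``iqr_ic50_rho == 0`` the same spread values
    are assigned in random order, independent of IC50.

    Returns ``(datasets, ic50_table)`` with ``datasets`` a dict
    ``line_id -> (CountMatrix, annotation, GroundTruth)`` and the IC50
    table a DataFrame with columns ``line_id`` and ``ic50_nM``.
    """
    ids = [s.line_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate line_id in panel specs")
    if len(specs) < 3:
        raise ValueError("panel needs at least 3 lines")
    rng = np.random.default_rng(seed)
    grid = np.linspace(*heterogeneity_range, num=len(specs))
    order = np.argsort([s.ic50 for s in specs], kind="stable")
    spreads = np.empty(len(specs))
    if iqr_ic50_rho > 0:
        spreads[order] = grid  # monotone with IC50
    else:
        spreads[:] = rng.permutation(grid)
    datasets = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, spread, child in zip(specs, spreads, child_seeds):
        spec = replace(spec, sensitive_program_sd=float(spread))
        datasets[spec.line_id] = simulate_line(
            spec, seed=int(child.generate_state(1)[0] % 2**31)
        )
    ic50 = pd.DataFrame({"line_id": ids, "ic50_nM": [s.ic50 for s in specs]})
    return datasets, ic50


def simulate_cohort(spec: SimCohortSpec, seed: int):
    """Simulate a patients x timepoints cohort with two response arms.

    Each patient carries a fixed multiplicative expression shift (log-normal
    per gene, sd ``patient_effect_sd``) shared by all of their cells at all
    timepoints.  Sensitive cells draw ``a_i ~ clip(Normal(0, h))`` and
    resistant cells ``a_i ~ clip(Normal(1, h * resistant_extra_heterogeneity))``
    so the extra-heterogeneity multiplier inflates only the within-arm
    spread of the resistance program.
    """
    rng = np.random.default_rng(seed)
    genes, _ = _gene_panel(
        spec.n_genes,
        spec.n_markers_up,
        spec.n_markers_down,
        spec.n_mito_genes,
        spec.n_ribo_genes,
        {},
    )
    up_ids = [g for g in genes if g.startswith("RESUP")]
    down_ids = [g for g in genes if g.startswith("RESDN")]
    mu = _baseline_means(
        rng, genes, spec.mito_mean_fraction,
        spec.marker_baseline_logmean, spec.marker_baseline_sd,
    )

    patients = [f"SPT{i+1:02d}" for i in range(spec.n_patients_sensitive)] + [
        f"RPT{i+1:02d}" for i in range(spec.n_patients_resistant)
    ]
    arm = {p: ("sensitive" if p.startswith("S") else "resistant") for p in patients}
    patient_shift = {
        p: rng.lognormal(0.0, spec.patient_effect_sd, size=len(genes))
        if spec.patient_effect_sd > 0
        else np.ones(len(genes))
        for p in patients
    }

    blocks, ann_rows, act_all, label_all, barcode_all = [], [], [], [], []
    h = spec.program_heterogeneity
    for patient in patients:
        resistant = arm[patient] == "resistant"
        scale = h * spec.resistant_extra_heterogeneity if resistant else h
        loc = 1.0 if resistant else 0.0
        for tp in spec.timepoints:
            m = spec.cells_per_patient_per_timepoint
            activation = _clipped_normal(rng, loc, scale, m)
            libsize = rng.lognormal(0.0, spec.libsize_lognorm_sd, size=m)
            lam = _expression_means(
                mu * patient_shift[patient],
                genes,
                activation,
                spec.effect_log2fc,
                up_ids,
                down_ids,
                libsize,
            )
            blocks.append(_nb_counts(rng, lam, spec.nb_dispersion))
            bc = [f"{patient}-{tp}-{i+1:04d}" for i in range(m)]
            barcode_all.extend(bc)
            ann_rows.append(
                pd.DataFrame(
                    {
                        "patient": patient,
                        "timepoint": tp,
                        "condition": arm[patient],
                    },
                    index=pd.Index(bc, name="barcode"),
                )
            )
            act_all.append(activation)
            label_all.extend(
                ["resistant" if resistant else "baseline"] * m
            )

    barcodes = pd.Index(barcode_all, name="barcode")
    matrix = CountMatrix(genes, barcodes, np.concatenate(blocks, axis=1))
    annotation = pd.concat(ann_rows)
    truth = GroundTruth(
        marker_up_ids=up_ids,
        marker_down_ids=down_ids,
        program_activation=pd.Series(
            np.concatenate(act_all), index=barcodes, name="activation"
        ),
        true_label=pd.Series(label_all, index=barcodes, name="true_label"),
    )
    return matrix, annotation, truth
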