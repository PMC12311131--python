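# scresist

Single-cell quantification of drug-resistance heterogeneity in paired
sensitive/resistant populations.

When a tumor cell line is driven to drug resistance, the resistant
derivative acquires a transcriptional program that distinguishes it from
its parental, drug-sensitive population. Two questions follow naturally
from single-cell RNA-seq of such pairs:

1. **Do resistance features pre-exist?** Are there cells inside the
   *sensitive* population that already express the resistant program
   ("resistant-like" cells), and does the breadth of that program across
   sensitive cells predict drug tolerance?
2. **How heterogeneous is resistance itself?** Do resistant populations
   split into distinct transcriptional sub-programs, and do resistant
   patients in a clinical cohort show wider cell-to-cell spread of
   resistance markers than sensitive patients?

`scresist` implements the full analysis chain for both questions, plus a
synthetic-data generator with known ground truth so every stage is
testable without any external download. It targets analysts working with
CDK4/6-inhibitor resistance in breast-cancer models, but nothing in the
code is specific to a drug or tissue.

## The statistics at the core

**Per-cell OLS similarity.** For each cell, expression `y` over a marker
panel (genes with pseudo-bulk |log2FC| ≥ 0.5 between resistant and
sensitive cells, restricted to the top variable genes) is regressed on the
two pseudo-bulk reference profiles with an intercept:

```
y ≈ β₀ + β_s·x_sensitive + β_r·x_resistant
```

Negative weights are clipped at zero and the similarity score is
`β_r / (β_s + β_r) ∈ [0, 1]`. Sensitive cells with score > 0.5 are called
**resistant-like**. Within-population heterogeneity is the inter-quartile
range (IQR) of scores; across a line panel the sensitive-population IQR is
correlated with drug IC50 by Spearman's ρ with an exact permutation
p-value at small n.

**Consensus markers.** A gene is *resistant-specific* when significantly
up-regulated (Wilcoxon rank-sum, BH-adjusted, `min.pct`/log2FC gates) in
resistant vs sensitive cells in ≥ 2 lines and never significantly
up-regulated in the opposite direction in any line; *sensitive-specific*
is symmetric.

**Distance heterogeneity.** For a group of cells, the average pairwise
euclidean distance on the marker genes among 1000 sampled cells, compared
against 100 size-matched random gene sets drawn from the top variable
genes excluding the markers — a null that asks whether the markers are
*specifically* dispersed.

Sub-structure inside resistant populations is found by Louvain community
detection on a Jaccard-weighted shared-nearest-neighbor graph in PCA
space over DE-filtered variable genes, and characterized by one-vs-rest
DE, hypergeometric over-representation, and mean-z signature scores.

## Worked example

```
$ python examples/03_panel_iqr_ic50.py
line   IC50(nM)   sensitive-score IQR
LINE1        50   0.0231
LINE2       100   0.0405
LINE3       150   0.0628
LINE4       200   0.0938
LINE5       250   0.1611
LINE6       300   0.1633
LINE7       350   0.1897
Spearman rho = 1.000, exact permutation p = 0.0004 (n=7)
```

Seven lines are simulated with the spread of the resistance-program
activation in their sensitive populations increasing with IC50. The full
pipeline (QC → normalization → DE → OLS gene selection → per-cell scoring
→ IQR → Spearman) recovers the planted link: lines whose sensitive cells
are more heterogeneous for resistance features tolerate more drug.

```
$ python examples/02_score_resistant_like_cells.py
OLS gene panel: 125 genes (|log2FC| >= 0.5 among top variable genes)
           n_cells     iqr  discordant_fraction
condition
resistant      493  0.0911               0.0203
sensitive      960  0.0180               0.0312
planted resistant-like fraction: 3.0%; recovered: 3.12%
30 of 31 planted resistant-like cells are called correctly
```

A planted 3% resistant-like subpopulation inside 1000 sensitive cells is
recovered at 3.12% with 30/31 cells called individually.

The other examples cover QC (`01`), consensus markers (`04`), resistant
sub-clustering (`05`) and the cohort analysis (`06`). A thin CLI wraps the
same stages (`scresist simulate|qc|markers|ols|cluster|cohort|all`); every
run writes a `manifest.json` with the seed and config hash from which it
can be reproduced exactly.

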