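# Methods

## Scope and data model

The pipeline operates on genes × cells UMI count matrices with per-cell
annotations (line or patient, sensitive/resistant condition, timepoint).
Two in-memory containers carry data between stages: `CountMatrix` (raw
integer counts with mito/ribo flags from symbol prefixes, `MT-` and
`RPL`/`RPS`, case-insensitive and configurable) and `NormalizedMatrix`
(log-normalized expression after mito/ribo removal). Readers accept a
10x-style MatrixMarket triplet or dense TSV; duplicate gene symbols are
collapsed by summation and logged.

## Quality control and normalization

A gene is *expressed* when its size-factor-scaled count
(`count / (total/median(total))`) is ≥ 0.1 in ≥ 10 cells; both boundaries
inclusive. Cells are retained when the number of expressed genes detected
lies in [2000, 7000] and the fraction of counts on mitochondrial genes is
≤ 10%, all inclusive. The gene-count band is evaluated over expressed
genes only; the mitochondrial fraction over all counts. Cells failing both
rules report the gene-count rule as the failure reason. For clinical
cohort data a lighter rule applies: ≥ 500 detected genes of any kind.

Normalization is global-scaling: `ln(1 + 10⁴·count/total)` with the total
over all genes (mitochondrial counts are real library mass), after which
mito and ribo rows are dropped. Regularized count-model normalization with
a mitochondrial covariate was deliberately not implemented — all bespoke
statistics downstream operate on any normalized matrix, and global scaling
keeps the pipeline dependency-light and exactly reproducible.

Variable genes are ranked by variance standardized against a
mean-variance trend (centered running median of per-gene variance ordered
by mean; window `max(31, n_genes/20)`), with raw-variance ranking
available via `method="variance"`. Zero-variance genes are never
selected; ties break lexicographically by symbol.

On the synthetic panels (≈1000 genes) the full-transcriptome defaults are
scaled accordingly: `min_genes=100`, `max_genes≈n_genes`,
`top_k_variable≈n_genes`. These are data-scale parameters, not new
thresholds — the rules themselves are unchanged.

## Differential expression and consensus markers

Group comparisons use a per-gene Wilcoxon rank-sum test (normal
approximation with tie correction) on log-normalized values, gated before
testing by `max(pct_a, pct_b) ≥ min_pct` (0.25 for line comparisons, 0.1
for cohort baseline DE) and `|log2FC| ≥ 0.25`, with BH adjustment over
tested genes only. Fold changes are computed on the de-logged scale with a
pseudocount of 1e−9 (arbitrary, configurable). The consensus rule over a
line panel: resistant-specific = significantly up-in-resistant
(`p_adj < 0.05`) in ≥ 2 lines and up-in-sensitive in none; symmetric for
sensitive-specific; output is invariant to line order.

Over-representation uses the hypergeometric upper tail
`P(X ≥ k)` with BH across sets. Signature activity is the per-cell mean of
per-gene z-scores (zero-variance genes contribute 0) — a deliberate
simplification of rank-based signature scoring; it is monotone in the
planted program and sufficient for every test in this package.

## OLS similarity and heterogeneity

The gene panel is the intersection of `|pseudo-bulk log2FC| ≥ 0.5`
(inclusive) with the top 2000 variable genes. Each cell is fitted by least
squares with an intercept against the sensitive and resistant pseudo-bulk
profiles; the two profile weights are clipped at zero (weights below
`1e−12` relative tolerance snap to zero so pure-profile cells score
exactly 0 or 1) and the score is `β_r/(β_s+β_r)`. Degenerate fits (both
weights ≤ 0) map to 0.5 with a flag so cell counts are conserved. The fit
rejects reference profiles with |correlation| > 0.999. Sensitive cells
with score strictly > 0.5 are resistant-like; resistant cells strictly
< 0.5 are sensitive-like; boundary cells stay unclassified.

Heterogeneity is the IQR of scores (linear-interpolation quantiles,
≥ 4 cells). The IQR–IC50 association uses Spearman's ρ with a two-sided
exact permutation p (all n! assignments) for panels of ≤ 9 lines — at
n = 7 the asymptotic approximation is unreliable — and the asymptotic p
beyond.

## Synthetic data generator

One mechanism drives everything: a per-cell program activation
`a ∈ [0, 1]`. Resistant cells draw `a ~ clip(Normal(1, h))` with
`h = program_heterogeneity` (default 0.25); sensitive cells sit at `a = 0`
except (i) a planted resistant-like fraction (default 3%, within the
few-percent range such subpopulations occupy) drawing from the resistant
distribution and (ii) an optional half-normal background spread
(`sensitive_program_sd`, default 0) that makes sensitive populations
continuously heterogeneous — the knob the panel generator ties
monotonically to IC50. Expected expression is
`λ = s·μ·2^(±effect·a)` on planted up/down markers (effect default 2,
i.e. four-fold) and `s·μ` elsewhere; `μ` is log-normal(0, 1) for
background genes and log-normal(1.5, 0.5) for markers — resistance
markers are by construction well-detected genes (they must pass the
25%-expressing DE gate), and placing them in the detectable stratum is
also what lets planted heterogeneity dominate the level-dependent noise
of log1p counts. `s` is a log-normal(0, 0.3) library factor; counts are
negative-binomial via gamma-Poisson with inverse-dispersion 5. A 10-gene
`MT-` block is rescaled to a 5% mean library share with per-cell
log-normal variation (sd 0.4) so the mitochondrial QC rule has work to
do; 20 `RPL` genes exercise ribosomal exclusion. Transcriptional
sub-structure is planted as disjoint per-cluster marker subsets switched
on only in that cluster's resistant cells.

The cohort generator adds per-patient multiplicative expression shifts
(log-normal per gene, sd 0.15, drawn once per patient and shared across
timepoints) and a `resistant_extra_heterogeneity` multiplier ≥ 1 on the
activation spread of resistant patients' cells. With mirror-symmetric
clipping (sensitive at 0, resistant at 1) both arms have activation
variance `≈ 0.34·(sd)²`, so the multiplier `m` inflates the resistant
variance by `m²` while clipping distortion stays small.

**What the generator does not emulate:** doublets, ambient RNA, batch
chemistry, copy-number structure, multi-dimensional resistance programs
(activation is a single axis), and realistic transcriptome size (panels
are ~1000 genes). Passing tests therefore demonstrate correctness of the
statistics and recoverability of planted structure, not robustness to
every real-data artifact. One real effect the generator *does* reproduce,
as a by-product of library-size normalization: when the resistance
program is on, every other gene's library share shrinks, so background
genes show a mild consistent "up in sensitive" shift — the consensus
sensitive-specific list consequently contains such compositional hits on
synthetic data. The planted markers themselves are recovered with
100% recall at default settings.

## Cohort analysis

Baseline (day 0) DE between arms feeds two analyses. First, per-cell OLS
against the two day-0 arm pseudo-bulks over the baseline DE genes. Besides
the bounded score, each cell gets an **own-arm similarity**
`1 − |w_own − 1|` where `w_own` is the raw (unclipped) mixture-weight
fraction of the cell's own arm profile. This choice is deliberate: the
clipped score collapses all cells more extreme than their own arm's
average into atoms at exactly 0 or 1, and with symmetric within-arm
spread those atoms cancel the inward tail in a rank test, leaving a
Wilcoxon comparison with essentially no power to see heterogeneity. The
folded raw weight instead converts spread in *either* direction into
lower similarity. Under a 3× planted spread the resistant arm is flagged
(lower similarity, one-sided p < 0.05) in essentially every replicate; at
equal spread the false-flag rate in that direction is conservative (the
small structural asymmetry between arms — they occupy different
expression regimes, so no per-cell fit statistic is exactly pivotal —
runs against the detected direction). Exact uniformity of the two-sample
p under the null is not attainable for any such statistic and is not
claimed.

Second, marker enrichment among DE genes is a two-sample proportion
z-test with continuity correction (capped at the observed difference, so
equal proportions give a zero statistic), one-sided for a greater marker
fraction among DE genes; and the distance statistic: sample up to 1000
cells per group (seeded, order-invariant), compute the mean pairwise
euclidean distance on marker genes, and compare with 100 random draws of
the same size from the top variable genes excluding markers, reusing the
same sampled cells so only the gene-set identity varies. The marker
statistic's position in the null is summarized as an empirical quantile;
"outside the central 95%" is judged by the standard add-one two-sided
permutation convention (p ≤ 0.05 ⇔ the statistic sits among the two most
extreme values of either tail of the combined 101). Calibration was
checked by a rank-uniformity diagnostic under an exchangeable-marker null
(program absent, markers drawn from the background stratum): the marker's
rank among the null draws is uniform.

## Clustering

Genes: variable genes restricted to the resistant-vs-sensitive DE list,
in variable-gene rank order. Cells are z-scored per gene, reduced to 20
principal components (deterministic full SVD), connected by a
Jaccard-weighted shared-nearest-neighbor graph (k = 20, self included,
prune < 1/15) and partitioned by Louvain modularity at resolution 0.6
(default; a grid is the user's choice — automatic resolution selection is
out of scope). Labels are relabeled by descending cluster size; the seed
fixes the traversal order so runs are reproducible. Characterization:
one-vs-rest DE per cluster (clusters < 3 cells skipped), ORA of each
cluster's significant up-genes against supplied gene sets with the
cluster's tested genes as universe, mean signature scores per cluster,
and a marker-table of top up-genes' mean expression across clusters.

## Numerical choices and degenerate inputs

Quantiles are linear-interpolation (type 7). BH is the standard step-up.
All-zero matrices yield an empty expressed-gene set with a warning; cells
with zero totals are rejected at normalization (they cannot survive QC).
Groups below 3 cells are rejected for DE; panels below 3 lines for the
IC50 correlation; fewer than 4 scores for the IQR. Test problem sizes
(≈250–1000 cells and 800–1200 genes per dataset; 100–200 sampled cells
for distance nulls) were chosen so the complete suite runs in a few
minutes on one CPU while every recovery margin stays wide.
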