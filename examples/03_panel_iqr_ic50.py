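"""Heterogeneity-IC50 correlation across a seven-line panel.

Lines whose sensitive population is more heterogeneous for the resistance
program (wider spread of OLS scores, measured as the inter-quartile range)
are simulated with higher drug IC50.  The full pipeline should recover the
monotone link as a strong positive Spearman correlation with an exact
permutation p-value.
"""

from scresist import RunConfig, SimLineSpec, simulate_panel
from scresist.pipeline import analyze_panel

specs = [
    SimLineSpec(line_id=f"LINE{i+1}", n_cells_sensitive=250,
                n_cells_resistant=250, n_genes=800, ic50=50.0 * (i + 1))
    for i in range(7)
]
datasets, ic50 = simulate_panel(specs, iqr_ic50_rho=1.0, seed=1)

config = RunConfig(min_genes=100, max_genes=1000, top_k_variable=800)
panel = analyze_panel(datasets, dict(zip(ic50["line_id"], ic50["ic50_nM"])), config)

print("line   IC50(nM)   sensitive-score IQR")
for line_id in sorted(panel.lines):
    print(f"{line_id:6s} {panel.ic50_by_line[line_id]:8.0f}   "
          f"{panel.iqr_by_line[line_id]:.4f}")
print(f"Spearman rho = {panel.rho:.3f}, exact permutation p = {panel.p:.4f} (n=7)")
print("-> sensitive-population heterogeneity tracks drug tolerance across lines")
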