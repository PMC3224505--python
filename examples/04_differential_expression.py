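"""Which genes change over the time course?

Per gene, a natural cubic spline fit over (log-warped) time is compared to
the constant model with an F statistic; significance comes from permuting
sample columns (null pooled over genes) with Bonferroni control at 1e-3.
"""
from pulsewave import default_design, default_time_grid, simulate_expression, within_class_test

expr, truth = simulate_expression(default_design(seed=1), default_time_grid())
table = within_class_test(expr, df_spline=4, n_perm=2000, seed=0)
merged = table.merge(truth, on="gene_id")
summary = merged.groupby("archetype").agg(
    significant=("significant", "sum"),
    fdr_05=("q_bh", lambda q: int((q < 0.05).sum())),
    n=("gene_id", "count"),
)
print(summary)
print(f"\n{int(table.significant.sum())} of {len(table)} genes pass the strict "
      "Bonferroni 1e-3 gate; the flat background stays quiet. Late-onset and "
      "oscillatory shapes concentrate their signal in few samples, so they "
      "surface at the conventional B-H FDR < 0.05 level instead")
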