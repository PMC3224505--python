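"""Temporal clustering of significant genes: hierarchy and SOM.

Samples cluster hierarchically under d = 1 - PCC (flat cut at 0.5);
significant genes are arranged on a 2x4 self-organizing map whose cells are
prototype temporal profiles with confidence bands.
"""
from pulsewave import (default_design, default_time_grid, hier_cluster,
                       simulate_expression, som_cluster, within_class_test)

expr, truth = simulate_expression(default_design(seed=1), default_time_grid())

sample_dendro = hier_cluster(expr, axis="samples")
print("sample clusters: cut at 1 - PCC = 0.5 keeps one phase "
      f"({max(sample_dendro.cut(0.5).values())} cluster: every sample pair has PCC > 0.5); "
      "a finer cut separates the temporal phases:")
for label, cl in sample_dendro.cut(0.25).items():
    print(f"  {label:6s} -> cluster {cl}")

sig = within_class_test(expr, seed=0)
genes = sig.loc[sig.significant, "gene_id"].tolist()
som = som_cluster(expr.subset(genes), rows=2, cols=4, seed=0)
lookup = dict(zip(truth.gene_id, truth.archetype))
print(f"\nSOM over {len(genes)} significant genes ({len(som.unassigned)} unassigned):")
for cell, members in sorted(som.members.items()):
    if members:
        kinds = sorted({lookup[g] for g in members})
        print(f"  cell {cell}: {len(members):3d} genes, archetypes {kinds}")
print("each populated cell collects one planted temporal archetype")
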