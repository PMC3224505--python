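"""Generate a synthetic impulse experiment with planted ground truth.

Writes the three standard input files (expression, interactome,
annotations) plus the truth table, then reloads them to show the round trip.
"""
from pathlib import Path

from pulsewave import (default_design, default_time_grid, read_expression,
                       simulate_annotations, simulate_expression, simulate_network,
                       write_annotations, write_expression, write_network)

out = Path("scratch_example_data")
out.mkdir(exist_ok=True)

design = default_design(seed=1)
grid = default_time_grid()
expr, truth = simulate_expression(design, grid)
network = simulate_network(truth, p_intra=0.3, p_inter=0.02, n_tf=20, seed=2)
annotations = simulate_annotations(truth, seed=3)

write_expression(expr, out / "expression.tsv")
write_network(network, out / "network.tsv")
write_annotations(annotations, out / "annotations.tsv")
truth.to_csv(out / "truth.tsv", sep="\t", index=False)

print(f"{expr.n_genes} genes x {len(expr.grid)} samples "
      f"({truth.module.nunique() - 1} planted modules + flat background)")
print(truth.groupby(['module', 'archetype']).size().to_string())
print(f"network: {len(network.nodes)} nodes, {network.n_edges} edges, {len(network.tf_set)} TFs")
reloaded = read_expression(out / "expression.tsv")
print("round trip exact:", (reloaded.values == expr.values).all())
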