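"""Build a multilayer peptidergic connectome and detect its modules.

Generates a cell-type expression table with three planted signaling
modules, connects peptide-expressing to receptor-expressing cell types
with weight sqrt(PeptideExpr * ReceptorExpr) * |log10 EC50|, runs Leiden
module detection, and ranks hub cell types by total strength.
"""

import peptidergic as pg
from peptidergic.connectome import build_network, detect_modules, hub_scores

spec = pg.ExpressionSpec(n_celltypes=12, background_expression=0.05, seed=0)
expr, truth_partition = pg.gen_expression(spec)
graph = build_network(expr, list(spec.pairs), expr_floor=0.0)
print(f"{len(expr)} cell types, {graph.number_of_edges()} directed edges in "
      f"{len({d['layer'] for _, _, d in graph.edges(data=True)})} layers")

modules = detect_modules(graph, resolution=1.0, seed=42)
print(f"detected {len(set(modules.values()))} modules "
      f"(planted: {truth_partition.nunique()})")

hubs = hub_scores(graph)
print("\nTop hub cell types (total incident edge strength):")
print(hubs.head(4).to_string(index=False))
print("\nEach layer is one peptide-receptor channel; module membership groups "
      "cell types that talk predominantly to each other.")
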