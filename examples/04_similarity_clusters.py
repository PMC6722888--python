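"""Cluster marker parameters within the mitotic cell population.

Pools the ground-truth mitotic (pHistone3+) cells of the default
experiment and computes pairwise Pearson correlations between nuclear
markers, the DNA-intercalator isotopes and the surface CD markers.
Complete-linkage clustering on 1 - r should place the co-regulated nuclear
trio (pHistone3 / Ki-67 / p4E-BP1) in one leaf block, the Ir isotopes
together, and the CD markers in their own block — the planted latent-factor
structure.  Edges with r > 0.3 are exported as a correlation graph.
"""

from imcprofiler import similarity as simi
from imcprofiler import synthetic as syn

rois = syn.generate_experiment(master_seed=42)
table = syn.experiment_table(rois)

params = (list(syn.MITOTIC_TRIO) + ["Ir191-DNA", "Ir193-DNA", "pH2A.X-S139",
                                    "p53"] + list(syn.MEMBRANE_CD_MARKERS))
sim = simi.pearson_matrix(table, params, population_filter="pHistone3+")
print(f"{sim.n_cells} mitotic cells")

order, Z = simi.hierarchical_order(sim)
print("clustered parameter order:")
print("  " + " | ".join(order))

graph = simi.edge_bundle_graph(sim, cutoff=0.3)
print(f"\ncorrelation graph (r > 0.3): {graph.number_of_edges()} edges")
for a, b, w in sorted(graph.edges(data="weight"), key=lambda e: -e[2])[:8]:
    print(f"  {a} -- {b}: r={w:.2f}")
print("\ndendrogram:", simi.linkage_to_newick(Z, sim.parameters)[:100], "...")
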