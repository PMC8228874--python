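"""Differential expression, volcano categories, and target networks.

Per-gene Welch tests with Bonferroni adjustment categorize genes by the
volcano color rules (red: adj. p < 0.05 and |log2FC| > 2; dark blue:
1.5 < |log2FC| <= 2; light blue: significant but small fold change).  Genes
upregulated in a subset (p < 0.05, log2FC > 1.5) are projected onto the
interaction table and summarised as edges/node and total connection score.
"""

from sclc_tme import (
    CohortSpec,
    PanelSpec,
    build_network,
    connectivity_stats,
    de_test,
    generate_cohort,
    generate_expression,
    generate_interactions,
    select_nodes,
    target_overlap,
)

samples, _ = generate_cohort(CohortSpec(seed=1))
panel = PanelSpec()
expr = generate_expression(samples, panel, seed=2)
edges = generate_interactions(panel, density=0.002, seed=3)
labels = expr.label_series("ne_subtype").to_dict()

de = de_test(expr.values, labels, "NE-low", "NE-high")
print("Volcano categories (NE-low vs NE-high):")
print(de["category"].value_counts().to_string())
top = de[de["category"] == "red"].nlargest(5, "log2fc")
print("\nStrongest NE-low-upregulated targets:")
print(top[["log2fc", "p_adj", "category"]].round(4).to_string())

up_low = select_nodes(de)
up_high = select_nodes(de.assign(log2fc=-de["log2fc"]))
print(f"\ntargets: {len(up_low)} up in NE-low, {len(up_high)} up in NE-high")
a_only, shared, b_only = target_overlap(up_low, up_high)
print(f"overlap check (must be disjoint): shared = {len(shared)}")

for name, nodes in (("NE-low", up_low), ("NE-high", up_high)):
    g = build_network(nodes, edges, min_score=0.4)
    s = connectivity_stats(g)
    print(f"{name} target network: {s.n_nodes} nodes, {s.n_edges} edges, "
          f"{s.edges_per_node:.2f} edges/node, "
          f"total connection score {s.total_connection_score:.2f}")
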