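"""Run the complete pipeline and tour the result bundle.

One call generates (or loads) all inputs and executes every stage in order;
the bundle holds each stage's table plus provenance metadata.  The same can
be run from a shell: ``sclc-tme all --seed 1 --out-dir results``.
"""

from sclc_tme import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, out_dir="scratch/example_results")
bundle = run_pipeline(config)

print("metadata:", bundle["metadata"])
print("\nphenotypes:")
print(bundle["phenotypes"]["phenotype"].value_counts().to_string())

print("\ntop of the z-scored pathway x group NES matrix:")
print(bundle["nes_matrix"].head(5).round(2).to_string())

print("\nmarker correlation grid (tumor-nest block):")
cols = [c for c in bundle["correlations"].columns if "tumor_nest" in c]
print(bundle["correlations"].loc[cols, cols].round(2).to_string())

print("\nnetwork connectivity per target set:")
for name, stats in bundle["network_stats"].items():
    print(f"  {name}: {stats['n_nodes']} nodes, "
          f"{stats['edges_per_node']:.2f} edges/node, "
          f"total score {stats['total_connection_score']:.2f}")
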