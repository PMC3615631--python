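"""Generate a benchmark-shaped synthetic dataset and summarize its
bipartite association network.

The generator plants phenotype clusters: diseases within a cluster are
more similar than diseases across clusters, and each miRNA draws most of
its associations from one home cluster.
"""

from omimwalk import benchmark_shaped_config, build_odman, generate, network_stats

sim, assoc, ground_truth = generate(benchmark_shaped_config(rng_seed=42))
stats = network_stats(build_odman(assoc))

print("diseases:", stats.n_diseases)
print("miRNAs:", stats.n_mirnas)
print("associations:", stats.n_associations)
row = stats.as_row()
print("average disease degree:", row["avg_degree_diseases"])
print("average miRNA degree:", row["avg_degree_mirnas"])
print("connected components:", stats.n_components)
print(f"largest component: {stats.largest_component_fraction:.1%} of nodes")
# The two averages are the exact quotients associations/diseases and
# associations/miRNAs; a disease is typically targeted by ~20 miRNAs while
# a miRNA is typically linked to ~3 diseases.
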