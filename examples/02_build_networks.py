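"""Reconstruct haplotype networks four ways from one small alignment.

Simulates a 4-haplotype diploid population, collapses the phased truth to
unique haplotypes, and prints the node/edge structure produced by the
minimum spanning network, median joining, statistical parsimony, and the
Fitch genealogy from a neighbor-joining guide tree.
"""

from hapnet import (
    SimSpec,
    build_guide_tree,
    collapse_haplotypes,
    fitch_genealogy,
    median_joining_network,
    minimum_spanning_network,
    pairwise_distances,
    simulate_dataset,
    tcs_connection_limit,
    tcs_network,
)

data = simulate_dataset(SimSpec(seed=20, K=4, n=30, L=200))
catalog = collapse_haplotypes(data.phased_truth)
dm = pairwise_distances(catalog)

print("haplotypes:", [(h.id, h.count) for h in catalog])
print("connection limit at 95% for L=200:", tcs_connection_limit(200, 0.95))

for name, graph in [
    ("MSN", minimum_spanning_network(dm, catalog)),
    ("MJN", median_joining_network(catalog, dm)),
    ("TCS", tcs_network(catalog, dm, threshold=0.95)),
    ("Fitch", fitch_genealogy(build_guide_tree(catalog, "nj"),
                              data.phased_truth, catalog)),
]:
    edges = sorted(graph.graph.edges(data="steps"))
    print(f"{name}: {len(graph.nodes)} nodes, total length "
          f"{graph.total_length}, edges {edges}")

# Total length is the summed mutational steps over all edges; TCS splits
# into subnetworks when haplotypes are further apart than the limit.
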