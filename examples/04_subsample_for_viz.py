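"""Shrink a large SSN to a visualization-friendly size.

Uniform edge sampling with graph induction, per connected component:
component count is preserved exactly, small components pass through
untouched, and reconnection uses only edges of the original graph, so
the output is always a subgraph.
"""

import networkx as nx

from ssnclose import SampleConfig, subsample_network

full = nx.disjoint_union_all(
    [nx.complete_graph(400), nx.gnm_random_graph(120, 360, seed=1), nx.complete_graph(8)]
)
cfg = SampleConfig(min_keep=10, fraction=0.25, seed=7)
small = subsample_network(full, cfg)

print(f"input : {full.number_of_nodes()} nodes, {full.number_of_edges()} edges, "
      f"{nx.number_connected_components(full)} components")
print(f"output: {small.number_of_nodes()} nodes, {small.number_of_edges()} edges, "
      f"{nx.number_connected_components(small)} components")
for comp in sorted(nx.connected_components(small), key=len, reverse=True):
    print(f"  component of {len(comp)} nodes "
          f"(connected: {nx.is_connected(small.subgraph(comp))})")
# The 8-node component is below min_keep and is returned as-is.
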