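"""Minimum connected PPI subnetwork and betweenness hubs.

Plants three connector hubs in a preferential-attachment interactome,
extracts the minimum connected network around a DEG seed set (Steiner-tree
approximation), and ranks nodes by exact betweenness centrality.
"""

from herbimeta import simulate_ppi
from herbimeta.networks import (
    minimum_connected_network,
    node_centralities,
    top_betweenness,
)

seeds = {f"deg_{i:02d}" for i in range(18)}
hub_plan = {
    "hub_a": [f"deg_{i:02d}" for i in range(6)],
    "hub_b": [f"deg_{i:02d}" for i in range(6, 12)],
    "hub_c": [f"deg_{i:02d}" for i in range(12, 18)],
}
network, truth = simulate_ppi(200, seeds, hub_plan, attach_m=2, seed=3)
print(f"interactome: {len(network.nodes)} nodes, {network.n_edges()} edges")

sub, dropped = minimum_connected_network(network, seeds)
print(f"minimum connected network: {len(sub.nodes)} nodes "
      f"({len(seeds)} seeds, {len(sub.nodes) - len(seeds)} linkers), "
      f"{len(dropped)} seeds unmapped")

stats = node_centralities(sub, seeds)
print("\ntop-5 betweenness (planted connectors marked *):")
for node in top_betweenness(stats, 5):
    mark = "*" if node in truth.hub_nodes else " "
    print(f" {mark}{node:>8}  btws={stats.at[node, 'betweenness']:7.1f}  "
          f"deg={stats.at[node, 'degree']}")
print("\nThe planted hubs are the connectors joining otherwise separate")
print("seed groups — high betweenness despite ordinary degree.")
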