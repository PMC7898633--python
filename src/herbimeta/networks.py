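"""Protein-protein interaction network analytics.

Operations on the score-filtered STRING-style interaction graph: minimum
connected subnetworks around DEG seed sets (a metric-closure Steiner-tree
2-approximation with fully deterministic tie-breaking), exact betweenness
centrality for connector-hub discovery, intersection of per-time-point hub
rankings, round-based neighbor expansion of a seed set, and a generic
hypergeometric enrichment test with Holm (Bonferroni step-down) correction.

Shortest paths are unweighted: the score filter (combined score > 900)
already binarizes confidence, so the filtered graph is treated purely
topologically.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PPINetwork

__all__ = [
    "ExpansionTrace",
    "minimum_connected_network",
    "steiner_forest",
    "node_centralities",
    "top_betweenness",
    "recurrent_hubs",
    "expand_network",
    "enrich_terms",
]


def _sorted_adjacency(g) -> dict[str, list[str]]:
    return {u: sorted(g[u]) for u in g}


def _bfs(adj: Mapping[str, list[str]], source: str):
    """Deterministic BFS: neighbors visited in lexicographic order."""
    dist = {source: 0}
    parent: dict[str, str | None] = {source: None}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
    return dist, parent


def _walk_up(parent: Mapping[str, str | None], node: str) -> list[str]:
    path = [node]
    while parent[node] is not None:
        node = parent[node]
        path.append(node)
    return path  # node .. source


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def steiner_forest(
    graph, seeds: Iterable[str]
) -> tuple[set[str], set[tuple[str, str]]]:
    """Metric-closure Steiner approximation, per connected component.

    For each component holding >= 2 seeds: compute seed-to-seed unweighted
    shortest-path distances (deterministic BFS), take the minimum spanning
    tree of that metric closure (Kruskal on (distance, u, v)-sorted edges),
    expand closure edges back into graph paths, re-extract a spanning tree
    of the expanded subgraph, and prune non-seed leaves.  Components with a
    single seed contribute that seed alone.  Returns the retained node set
    and the retained tree edges (canonical pairs).
    """
    import networkx as nx

    seeds = set(seeds)
    retained: set[str] = set()
    tree_edges: set[tuple[str, str]] = set()
    for comp in nx.connected_components(graph):
        comp_seeds = sorted(seeds & comp)
        if not comp_seeds:
            continue
        if len(comp_seeds) == 1:
            retained.add(comp_seeds[0])
            continue
        sub = graph.subgraph(comp)
        adj = _sorted_adjacency(sub)
        bfs = {s: _bfs(adj, s) for s in comp_seeds}
        closure = sorted(
            (bfs[s][0][t], s, t)
            for i, s in enumerate(comp_seeds)
            for t in comp_seeds[i + 1:]
        )
        uf = _UnionFind(comp_seeds)
        expanded = nx.Graph()
        for d, s, t in closure:
            if uf.union(s, t):
                path = _walk_up(bfs[s][1], t)  # t .. s
                expanded.add_edges_from(zip(path, path[1:]))
        # spanning tree of the expanded subgraph, then prune non-seed leaves
        uf2 = _UnionFind(expanded.nodes)
        tree = nx.Graph()
        tree.add_nodes_from(expanded.nodes)
        for u, v in sorted(tuple(sorted(e)) for e in expanded.edges):
            if uf2.union(u, v):
                tree.add_edge(u, v)
        while True:
            leaves = [v for v in tree
                      if tree.degree(v) <= 1 and v not in seeds]
            if not leaves:
                break
            tree.remove_nodes_from(leaves)
        retained |= set(tree.nodes)
        tree_edges |= {tuple(sorted(e)) for e in tree.edges}
    return retained, tree_edges


def minimum_connected_network(
    network: PPINetwork,
    seeds: Iterable[str],
    induced_edges: bool = True,
) -> tuple[PPINetwork, set[str]]:
    """Smallest practical subnetwork connecting the mapped seed genes.

    Seeds absent from the graph are returned as ``dropped_seeds``.  The
    retained node set comes from :func:`steiner_forest`; by default all
    original edges among retained nodes are restored (``induced_edges``),
    otherwise only the Steiner tree edges are kept.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    if not network.nodes:
        raise ValueError("empty network")
    mapped = seeds & network.nodes
    dropped = seeds - network.nodes
    if not mapped:
        return PPINetwork(), dropped
    g = network.to_networkx()
    retained, tree_edges = steiner_forest(g, mapped)
    if induced_edges:
        sub = network.subgraph(retained)
    else:
        sub = PPINetwork(nodes=set(retained))
        for a, b in tree_edges:
            sub.edges[(a, b)] = network.edges[(a, b)]
    for node in retained:
        sub.add_node(node)
    return sub, dropped


def node_centralities(
    subnetwork: PPINetwork,
    seeds: Iterable[str] = (),
    expression: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Degree and exact betweenness per node, with seed/expression flags.

    Betweenness is the unnormalized Brandes count over unordered node pairs
    on the unweighted graph.  ``expression`` maps nodes to their log2FC;
    nodes without an entry get NaN (the "not altered" marker of linker
    nodes pulled in only to connect the network).
    """
    import networkx as nx

    g = subnetwork.to_networkx()
    seeds = set(seeds)
    expression = expression or {}
    btw = nx.betweenness_centrality(g, normalized=False)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [g.degree(n) for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "is_seed": [n in seeds for n in nodes],
            "expression": [expression.get(n, np.nan) for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def top_betweenness(stats: pd.DataFrame, n: int = 15) -> list[str]:
    """The ``n`` nodes with the highest betweenness.

    Ties break by descending degree, then lexicographic node id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(
        stats.index,
        key=lambda node: (-stats.at[node, "betweenness"],
                          -stats.at[node, "degree"], node),
    )
    return order[:n]


def recurrent_hubs(rankings: Sequence[Iterable[str]]) -> set[str]:
    """Nodes present in every ranking (order-free intersection)."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings")
    sets = [set(r) for r in rankings]
    return set.intersection(*sets)


@dataclass
class ExpansionTrace:
    initial: set[str]
    rounds: list[list[tuple[str, int]]]  # per round: (node, attachment score)
    subnetwork: PPINetwork
    truncated: bool = False

    def nodes_after_round(self, r: int) -> set[str]:
        nodes = set(self.initial)
        for added in self.rounds[:r]:
            nodes |= {n for n, _ in added}
        return nodes


def expand_network(
    network: PPINetwork,
    seeds: Iterable[str],
    rounds: int = 6,
    per_round: int = 5,
) -> ExpansionTrace:
    """Grow a seed set by repeatedly adding the best-attached neighbors.

    Each round scores every non-member neighbor by the summed combined
    scores of its edges into the current member set and admits the
    ``per_round`` top candidates (score ties break lexicographically).
    Edges among members are always induced from the full network.  Stops
    early (``truncated=True``) when no addable neighbor remains.
    """
    if rounds < 1 or per_round < 1:
        raise ValueError("rounds and per_round must be >= 1")
    g = network.to_networkx()
    members = {s for s in seeds if s in network.nodes}
    initial = set(members)
    trace: list[list[tuple[str, int]]] = []
    truncated = False
    for _ in range(rounds):
        scores: dict[str, int] = {}
        for m in members:
            for nb in g[m]:
                if nb in members:
                    continue
                scores[nb] = scores.get(nb, 0) + g[m][nb]["combined_score"]
        if not scores:
            truncated = True
            break
        chosen = sorted(scores.items(), key=lambda t: (-t[1], t[0]))[:per_round]
        trace.append([(node, int(score)) for node, score in chosen])
        members |= {node for node, _ in chosen}
    sub = network.subgraph(members)
    for m in members:
        sub.add_node(m)
    return ExpansionTrace(initial=initial, rounds=trace, subnetwork=sub,
                          truncated=truncated)


def enrich_terms(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation test with Holm correction.

    For each term, the p-value is the upper tail
    ``P(overlap >= observed)`` of the hypergeometric distribution on
    (|universe|, |term ∩ universe|, |query|).  Terms with zero overlap are
    skipped.  Adjusted p-values use the Bonferroni step-down (Holm)
    procedure across the tested terms.
    """
    from scipy.stats import hypergeom
    from statsmodels.stats.multitest import multipletests

    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError(
            f"query genes outside universe: {sorted(query - universe)[:5]}"
        )
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe
        overlap = len(term_genes & query)
        if overlap == 0:
            continue
        p = float(hypergeom.sf(overlap - 1, len(universe), len(term_genes),
                               len(query)))
        rows.append((term, overlap, len(term_genes), p))
    if not rows:
        return pd.DataFrame(
            columns=["term", "overlap", "term_size", "p", "p_adjusted"]
        ).set_index("term")
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    df["p_adjusted"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    df = df.sort_values(["p", "term"]).set_index("term")
    return df
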