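"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive — exhaustive enumeration, literal
textbook formulas, stdlib-only numerics where possible — so that agreement
with the package is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from statistics import NormalDist

import numpy as np


def brute_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness over unordered pairs by explicit
    enumeration of every shortest path."""
    nodes = sorted(adj)
    btw = {v: 0.0 for v in nodes}

    def all_shortest_paths(s, t):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return [p for p in paths if p[-1] == t and len(p) - 1 == dist[t]]

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                btw[v] += through / len(paths)
    return btw


def brute_steiner_edges(adj: dict, seeds: set) -> int | None:
    """Minimum number of edges of any connected subgraph spanning the
    seeds, by exhaustive enumeration of node supersets.

    Any Steiner tree on node set S has |S| - 1 edges and requires the
    induced subgraph on S to be connected, so the optimum is
    min |S| - 1 over connected supersets.  Returns None when the seeds
    cannot be connected.
    """
    nodes = sorted(adj)
    extras = [v for v in nodes if v not in seeds]
    if not seeds:
        return 0

    def connected(sub: set) -> bool:
        start = next(iter(sub))
        seen = {start}
        q = deque([start])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v in sub and v not in seen:
                    seen.add(v)
                    q.append(v)
        return seen == sub

    for extra_count in range(len(extras) + 1):
        best = None
        for combo in itertools.combinations(extras, extra_count):
            sub = set(seeds) | set(combo)
            if connected(sub):
                best = len(sub) - 1
                break
        if best is not None:
            return best
    return None


def brute_venn(named_sets: dict) -> dict:
    """Per-element membership-signature tally."""
    names = list(named_sets)
    universe = set().union(*[set(s) for s in named_sets.values()]) \
        if named_sets else set()
    counts: dict[frozenset, int] = {}
    for el in universe:
        sig = frozenset(n for n in names if el in set(named_sets[n]))
        counts[sig] = counts.get(sig, 0) + 1
    return counts


def hypergeom_upper_tail(M: int, K: int, N: int, k: int) -> float:
    """P(overlap >= k) for |universe|=M, |term|=K, |query|=N, exact combinatorics."""
    total = math.comb(M, N)
    acc = 0
    for j in range(k, min(K, N) + 1):
        acc += math.comb(K, j) * math.comb(M - K, N - j)
    return acc / total


def bca_oracle(values, B: int, alpha: float, seed: int):
    """Second, independent BCa implementation (stdlib normal quantiles,
    hand-rolled type-7 quantile).  Shares the resample-index scheme with
    the implementation so endpoint comparison is exact up to numerics."""
    nd = NormalDist()
    x = np.asarray(values, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot = np.sort(x[idx].mean(axis=1))
    theta = x.mean()
    p = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / B
    p = min(max(p, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = nd.inv_cdf(p)
    jack = np.array([np.delete(x, i).mean() for i in range(n)])
    d = jack.mean() - jack
    a = (d**3).sum() / (6.0 * ((d**2).sum()) ** 1.5)

    def type7(level: float) -> float:
        h = (B - 1) * level
        lo = int(math.floor(h))
        hi = min(lo + 1, B - 1)
        return float(boot[lo] + (h - lo) * (boot[hi] - boot[lo]))

    z_lo, z_hi = nd.inv_cdf(alpha / 2), nd.inv_cdf(1 - alpha / 2)
    a1 = nd.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = nd.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    return type7(a1), type7(a2), z0, a


def random_graph(rng: np.random.Generator, n_max: int = 8,
                 p: float = 0.4, connected: bool = True) -> dict:
    """Random adjacency dict on string nodes, optionally forced connected."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        nodes = [f"n{i}" for i in range(n)]
        adj = {v: set() for v in nodes}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    adj[nodes[i]].add(nodes[j])
                    adj[nodes[j]].add(nodes[i])
        if not connected:
            return {v: sorted(a) for v, a in adj.items()}
        seen = {nodes[0]}
        q = deque([nodes[0]])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    q.append(v)
        if len(seen) == n:
            return {v: sorted(a) for v, a in adj.items()}
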