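"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the package's own code paths (and, where easy,
its libraries) so each check is a genuine dual route.
"""

from __future__ import annotations

import itertools
from math import comb


def shortest_paths_by_enumeration(nodes, edges):
    """All-pairs shortest path lengths by enumerating all simple paths.

    Only sane for <= ~7 nodes.  Returns {(u, v): length} for reachable
    ordered pairs with u < v; d(u, u) = 0 implied.
    """
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)

    def simple_paths(start, goal):
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            if node == goal:
                yield path
                continue
            for nxt in adjacency[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    out = {}
    nodes = sorted(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            lengths = [len(p) - 1 for p in simple_paths(u, v)]
            if lengths:
                out[(u, v)] = min(lengths)
    return out


def normalized_ranks_by_sorting(values: dict) -> dict:
    """Average-tie normalized ranks via explicit sorting, no scipy."""
    n = len(values)
    ordered = sorted(values.items(), key=lambda kv: kv[1])
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and ordered[j][1] == ordered[i][1]:
            j += 1
        avg = (i + 1 + j) / 2  # mean of ranks i+1 .. j
        for k in range(i, j):
            ranks[ordered[k][0]] = avg / n
        i = j
    return ranks


def statistic_by_pair_enumeration(rho_node, distances, lambda_decay, max_distance):
    """Topology-weighted statistic by naive enumeration over ordered pairs."""
    nodes = list(rho_node)
    total = sum(rho_node.values())
    for u, v in itertools.combinations(nodes, 2):
        d = distances.get((u, v)) or distances.get((v, u))
        if d is not None and 1 <= d <= max_distance:
            total += lambda_decay ** (d - 1) * rho_node[u] * rho_node[v]
    return total


def upper_tail_by_enumeration(X, M, K, N):
    """P(|A & B| >= X) for uniformly random K-subset A vs fixed N-subset B,
    by enumerating all C(M, K) subsets."""
    disease = set(range(N))
    hits = sum(
        1 for subset in itertools.combinations(range(M), K)
        if len(disease.intersection(subset)) >= X
    )
    return hits / comb(M, K)
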