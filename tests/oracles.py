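"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles (exhaustive enumeration,
closed forms) and deliberately shares no code path with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# graph oracles (adjacency given as dict node -> set of neighbours)


def adjacency(edges, nodes=None):
    adj = {n: set() for n in (nodes or [])}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bf_shortest_paths(adj, source):
    """All shortest paths from source: (distance map, path-count map)."""
    dist = {source: 0}
    paths = {source: [[source]]}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in sorted(adj[u]):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        for w in nxt:
            paths[w] = [
                p + [w] for u in adj[w] if dist.get(u) == dist[w] - 1 for p in paths[u]
            ]
        frontier = nxt
    return dist, paths


def bf_degree(adj):
    return {n: len(nbrs) for n, nbrs in adj.items()}


def bf_closeness(adj):
    out = {}
    for n in adj:
        dist, _ = bf_shortest_paths(adj, n)
        out[n] = 1.0 / sum(dist.values())
    return out


def bf_betweenness(adj):
    """Raw betweenness: enumerate every shortest path of every unordered pair."""
    nodes = sorted(adj)
    out = {n: 0.0 for n in nodes}
    for j, k in itertools.combinations(nodes, 2):
        _, paths = bf_shortest_paths(adj, j)
        if k not in paths:
            continue
        all_paths = paths[k]
        for i in nodes:
            if i in (j, k):
                continue
            through = sum(1 for p in all_paths if i in p[1:-1])
            out[i] += through / len(all_paths)
    return out


def bf_clustering(adj):
    out = {}
    for n, nbrs in adj.items():
        d = len(nbrs)
        if d < 2:
            out[n] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a]
        )
        out[n] = links / comb(d, 2)
    return out


# ---------------------------------------------------------------------------
# exact permutation null by exhaustive enumeration


def exact_null_pvalues(n_nodes, edge_u, edge_v, weights):
    """Exact P-values over all |E|! weight-to-edge assignments.

    Only feasible for tiny networks (<= ~7 edges).
    """
    weights = np.asarray(weights, dtype=float)
    n_edges = len(weights)
    observed = np.zeros(n_nodes)
    for (a, b, w) in zip(edge_u, edge_v, weights):
        observed[a] += w
        observed[b] += w
    hits = np.zeros(n_nodes, dtype=int)
    total = 0
    # round before comparing so that mathematical ties (same multiset of
    # weights summed in a different order) are counted as ties
    obs_r = np.round(observed, 9)
    for perm in itertools.permutations(range(n_edges)):
        null = np.zeros(n_nodes)
        for slot, src in enumerate(perm):
            null[edge_u[slot]] += weights[src]
            null[edge_v[slot]] += weights[src]
        hits += np.round(null, 9) >= obs_r
        total += 1
    return hits / total


def reachable_assignments(edge_u, edge_v, n_attempt_rounds=None):
    """All weight assignments reachable by node-disjoint edge-pair swaps.

    BFS over permutations of edge slots, starting from the identity, using
    only transpositions of node-disjoint edge pairs.
    """
    n_edges = len(edge_u)
    disjoint = [
        (a, b)
        for a, b in itertools.combinations(range(n_edges), 2)
        if len({edge_u[a], edge_v[a], edge_u[b], edge_v[b]}) == 4
    ]
    start = tuple(range(n_edges))
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for perm in frontier:
            for a, b in disjoint:
                new = list(perm)
                new[a], new[b] = new[b], new[a]
                new = tuple(new)
                if new not in seen:
                    seen.add(new)
                    nxt.append(new)
        frontier = nxt
    return seen


# ---------------------------------------------------------------------------
# exact hypergeometric tail by enumeration


def exact_overrep_pvalue(universe, term, selection_size, observed_k):
    """P(overlap >= k) over all equally likely selections of the given size."""
    universe = sorted(universe)
    term = set(term)
    hits = 0
    total = 0
    for sel in itertools.combinations(universe, selection_size):
        total += 1
        if len(term & set(sel)) >= observed_k:
            hits += 1
    return hits / total
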