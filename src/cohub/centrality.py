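"""Classical node-centrality scores on binary co-expression networks.

Four standard measures of a gene's topological prominence in the
percentile-thresholded (unweighted) network, plus the helpers used to
compare the gene sets they select.

Conventions (fixed to the plain textbook formulas, not to any particular
network tool's defaults):

* closeness is the inverse of the sum of shortest-path distances to the
  other nodes of the node's *connected component*;
* betweenness is the raw (unnormalized) sum over unordered node pairs of
  the fraction of shortest paths through the node — an optional flag
  divides by C(n-1, 2), a monotone rescaling that cannot change any
  percentile-based selection;
* the clustering coefficient of a degree-0 or degree-1 node is reported
  as 0 (the denominator C(deg, 2) vanishes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .network import BinaryNetwork, nearest_rank_threshold

__all__ = [
    "degree",
    "closeness",
    "betweenness",
    "clustering_coefficient",
    "centrality_table",
    "select_top_percentile",
    "set_overlap",
    "OverlapReport",
]


def degree(net: BinaryNetwork) -> dict[str, int]:
    """Number of nodes connected to each gene."""
    g = net.to_networkx()
    return {n: int(d) for n, d in g.degree()}


def closeness(net: BinaryNetwork) -> dict[str, float]:
    """1 / (sum of shortest distances to the other nodes of the component)."""
    g = net.to_networkx()
    out = {}
    for node in net.node_ids:
        dist = nx.single_source_shortest_path_length(g, node)
        total = sum(dist.values())  # distance to self is 0
        out[node] = 1.0 / total
    return out


def betweenness(net: BinaryNetwork, normalized: bool = False) -> dict[str, float]:
    """Sum over unordered pairs {j, k} of the shortest-path fraction via i."""
    g = net.to_networkx()
    raw = nx.betweenness_centrality(g, normalized=False)
    if normalized:
        n = net.n_nodes
        denom = math.comb(n - 1, 2) if n > 2 else 1
        return {node: b / denom for node, b in raw.items()}
    return {node: float(b) for node, b in raw.items()}


def clustering_coefficient(net: BinaryNetwork) -> dict[str, float]:
    """Edge density among each node's neighbours; 0 when degree < 2."""
    g = net.to_networkx()
    return {n: float(c) for n, c in nx.clustering(g).items()}


def centrality_table(net: BinaryNetwork) -> pd.DataFrame:
    """All four centrality scores, one row per gene, gene id ascending."""
    d = degree(net)
    c = closeness(net)
    b = betweenness(net)
    u = clustering_coefficient(net)
    genes = sorted(net.node_ids)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "degree": [d[g] for g in genes],
            "closeness": [c[g] for g in genes],
            "betweenness": [b[g] for g in genes],
            "clustering": [u[g] for g in genes],
        }
    )


def select_top_percentile(
    scores: Mapping[str, float], percentile: float = 0.95
) -> set[str]:
    """Genes scoring at or above the nearest-rank percentile of the scores.

    Uses the same nearest-rank convention as network thresholding; with
    heavy ties the returned set may exceed (1 - percentile) of the genes.
    """
    if not scores:
        raise ValueError("cannot select from an empty score map")
    values = np.array(list(scores.values()), dtype=float)
    thr = nearest_rank_threshold(values, percentile)
    return {g for g, s in scores.items() if s >= thr}


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise intersection sizes between named gene sets.

    ``pairwise`` has one row per unordered pair of set names (columns
    set_a, set_b, overlap, size_a, size_b); ``common`` is the intersection
    of all the sets.
    """

    pairwise: pd.DataFrame
    common: frozenset[str]


def set_overlap(sets: Mapping[str, set[str]]) -> OverlapReport:
    """Compare >= 2 named gene sets: all pairwise overlaps + the common core."""
    if len(sets) < 2:
        raise ValueError("need at least two named gene sets")
    names = list(sets)
    rows = []
    for a, b in combinations(names, 2):
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "overlap": len(set(sets[a]) & set(sets[b])),
                "size_a": len(sets[a]),
                "size_b": len(sets[b]),
            }
        )
    common = frozenset.intersection(*(frozenset(s) for s in sets.values()))
    return OverlapReport(pairwise=pd.DataFrame(rows), common=common)
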