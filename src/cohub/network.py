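"""Construction of weighted and thresholded gene co-expression networks.

A weighted co-expression network is the complete graph over the genes of an
expression matrix, with each edge weighted by the absolute Pearson
correlation of the two expression profiles.  The binary (unweighted)
network keeps only the edges whose weight reaches a chosen percentile of
the observed weight distribution; classical centrality scores operate on
that graph, while weighted node connectivity operates on the full weighted
graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


__all__ = [
    "ExpressionMatrix",
    "WeightedNetwork",
    "BinaryNetwork",
    "compute_correlation_network",
    "threshold_network",
    "nearest_rank_threshold",
]


class NetworkError(ValueError):
    """Raised for invalid network or expression-matrix inputs."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample numeric expression table.

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers, unique and ordered.
    sample_ids : sequence of str
        Column identifiers, unique and ordered.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; units are arbitrary (log scale assumed but not
        enforced).  Missing values are rejected: Pearson correlation over
        incomplete profiles has no single agreed definition and silent
        imputation would corrupt downstream hub ranking.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        if len(set(genes)) != len(genes):
            raise NetworkError("duplicate gene identifiers in expression matrix")
        if len(set(samples)) != len(samples):
            raise NetworkError("duplicate sample identifiers in expression matrix")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(genes), len(samples)):
            raise NetworkError(
                f"expression values have shape {values.shape}, expected "
                f"({len(genes)}, {len(samples)})"
            )
        if len(samples) < 3:
            raise NetworkError(
                "at least 3 samples are required for Pearson correlation; "
                f"got {len(samples)}"
            )
        if not np.isfinite(values).all():
            bad = [genes[i] for i in np.unique(np.nonzero(~np.isfinite(values))[0])]
            raise NetworkError(
                "missing or non-finite expression values for genes: "
                + ", ".join(bad[:10])
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _canonical_edges(
    node_index: Mapping[str, int],
    edges: Iterable[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray]:
    u_idx, v_idx = [], []
    for a, b in edges:
        if a == b:
            raise NetworkError(f"self-edge on node {a!r}")
        ia, ib = node_index[str(a)], node_index[str(b)]
        if ia > ib:
            ia, ib = ib, ia
        u_idx.append(ia)
        v_idx.append(ib)
    u = np.asarray(u_idx, dtype=np.int64)
    v = np.asarray(v_idx, dtype=np.int64)
    n = len(node_index)
    keys = u * n + v
    if len(np.unique(keys)) != len(keys):
        raise NetworkError("duplicate edges (same unordered node pair)")
    return u, v


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected graph over gene identifiers with edge weights in [0, 1].

    Edges are stored in canonical form (``edge_u[k] < edge_v[k]`` as node
    indices); ``weights[k]`` is the weight of the k-th edge.
    """

    node_ids: tuple[str, ...]
    edge_u: np.ndarray = field(repr=False)
    edge_v: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any() or (w > 1).any() or not np.isfinite(w).all():
            raise NetworkError("edge weights must lie in [0, 1]")
        if not (len(self.edge_u) == len(self.edge_v) == len(w)):
            raise NetworkError("edge arrays have inconsistent lengths")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Sequence[str] | None = None,
    ) -> "WeightedNetwork":
        edges = [(str(a), str(b), float(w)) for a, b, w in edges]
        if nodes is None:
            seen: dict[str, None] = {}
            for a, b, _ in edges:
                seen.setdefault(a)
                seen.setdefault(b)
            nodes = list(seen)
        node_ids = tuple(str(n) for n in nodes)
        if len(set(node_ids)) != len(node_ids):
            raise NetworkError("duplicate node identifiers")
        index = {n: i for i, n in enumerate(node_ids)}
        u, v = _canonical_edges(index, [(a, b) for a, b, _ in edges])
        w = np.array([w for _, _, w in edges], dtype=float)
        return cls(node_ids, u, v, w)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def degrees(self) -> np.ndarray:
        """Number of incident edges per node, in node order."""
        d = np.bincount(self.edge_u, minlength=self.n_nodes)
        d += np.bincount(self.edge_v, minlength=self.n_nodes)
        return d

    def edge_iter(self) -> Iterable[tuple[str, str, float]]:
        for a, b, w in zip(self.edge_u, self.edge_v, self.weights):
            yield self.node_ids[a], self.node_ids[b], float(w)

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """Same topology with a new weight vector (used by the null model)."""
        return WeightedNetwork(self.node_ids, self.edge_u, self.edge_v, weights)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_weighted_edges_from(self.edge_iter())
        return g


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected unweighted graph; every node is guaranteed degree >= 1.

    Isolated nodes are dropped at construction: a node that loses all its
    edges at thresholding leaves the network (this is why thresholded
    networks typically have fewer nodes than their weighted source).
    """

    node_ids: tuple[str, ...]
    edge_u: np.ndarray = field(repr=False)
    edge_v: np.ndarray = field(repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
    ) -> "BinaryNetwork":
        edges = [(str(a), str(b)) for a, b in edges]
        connected: dict[str, None] = {}
        for a, b in edges:
            connected.setdefault(a)
            connected.setdefault(b)
        if nodes is None:
            node_ids = tuple(connected)
        else:
            # keep the caller's node order, but drop isolated nodes
            node_ids = tuple(str(n) for n in nodes if str(n) in connected)
        index = {n: i for i, n in enumerate(node_ids)}
        u, v = _canonical_edges(index, edges)
        return cls(node_ids, u, v)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_u)

    def edge_iter(self) -> Iterable[tuple[str, str]]:
        for a, b in zip(self.edge_u, self.edge_v):
            yield self.node_ids[a], self.node_ids[b]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edge_iter())
        return g


def compute_correlation_network(expr: ExpressionMatrix) -> WeightedNetwork:
    """Build the complete absolute-Pearson co-expression network.

    Every pair of genes is connected; the edge weight is
    ``|pearson(profile_i, profile_j)|``.  Constant expression profiles make
    the correlation undefined and are rejected by name rather than mapped
    to weight 0, since silent zeros would distort hub ranking.
    """
    values = expr.values
    sd = values.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = ", ".join(expr.gene_ids[i] for i in flat[:10])
        raise NetworkError(f"zero-variance expression profile for gene(s): {names}")
    n = expr.n_genes
    if n < 2:
        raise NetworkError("need at least 2 genes to build a network")
    corr = np.corrcoef(values)
    u, v = np.triu_indices(n, k=1)
    # |r| can exceed 1 by an ulp in floating point; clip, don't reject
    w = np.clip(np.abs(corr[u, v]), 0.0, 1.0)
    return WeightedNetwork(expr.gene_ids, u.astype(np.int64), v.astype(np.int64), w)


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the order statistic at rank ceil(p * n).

    With distinct values this leaves a fraction of roughly ``1 - p`` of the
    values at or above the returned threshold.
    """
    if not 0.0 < percentile < 1.0:
        raise NetworkError(f"percentile must be in (0, 1); got {percentile}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NetworkError("cannot take a percentile of an empty set")
    rank = math.ceil(percentile * values.size)  # 1-based
    return float(np.sort(values)[rank - 1])


def threshold_network(net: WeightedNetwork, percentile: float = 0.95) -> BinaryNetwork:
    """Binarize a weighted network at a percentile of its weight distribution.

    Edges with weight >= the nearest-rank percentile threshold are kept
    (ties at the threshold are all retained); nodes left without any edge
    are removed.
    """
    if net.n_edges == 0:
        raise NetworkError("cannot threshold a network with no edges")
    thr = nearest_rank_threshold(net.weights, percentile)
    keep = net.weights >= thr
    edges = [
        (net.node_ids[a], net.node_ids[b])
        for a, b in zip(net.edge_u[keep], net.edge_v[keep])
    ]
    return BinaryNetwork.from_edges(edges, nodes=net.node_ids)
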