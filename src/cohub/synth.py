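"""Seeded generators of synthetic expression data and random networks.

The expression generator plants *hub modules*: groups of genes that share
a latent standard-normal driver and are therefore mutually correlated,
embedded among background genes that are independent noise.  The few-
sample regime it emulates (defaults: 10 samples, a few hundred genes)
matches typical small co-expression studies; it deliberately models no
platform artifacts (normalization, library size, batch), so results on it
speak to the statistics of the method, not to data cleaning.

Each module gene is built as

    x = noise_sd * ( sqrt(lam) * driver + sqrt(1 - lam) * eps ),
    lam = driver_strength**2

with ``eps`` i.i.d. standard normal per gene, so the population
correlation of a module gene with its driver is exactly
``driver_strength`` and the within-module pairwise correlation is
``driver_strength**2``.  Background genes are ``noise_sd * eps``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .network import ExpressionMatrix, WeightedNetwork

__all__ = ["HubSpec", "generate_expression", "generate_random_network"]


@dataclass(frozen=True)
class HubSpec:
    """Parameters of a planted-hub synthetic expression matrix.

    Parameters
    ----------
    n_genes : int
        Total genes (modules plus background).
    n_samples : int
        Samples per gene; default 10, the scale of a small expression study.
    n_hubs : int
        Number of planted modules, each with its own independent driver.
    module_size : int
        Genes per module; ``n_hubs * module_size <= n_genes``.
    driver_strength : float in (0, 1)
        Target |correlation| of each module gene with its latent driver.
    noise_sd : float > 0
        Marginal scale of every gene (correlations are scale-free, so this
        only matters if the matrix is inspected directly).
    seed : int
        Fixes the generated matrix exactly.
    negative_loadings : bool
        If True, every other gene within a module has its driver loading
        sign-flipped, producing strong *negative* within-module
        correlations — exercises the absolute-value weighting path.
    """

    n_genes: int
    n_samples: int = 10
    n_hubs: int = 2
    module_size: int = 15
    driver_strength: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0
    negative_loadings: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 3:
            raise ValueError("need n_genes >= 1 and n_samples >= 3")
        if self.n_hubs < 0 or (self.n_hubs > 0 and self.module_size < 1):
            raise ValueError("invalid module layout")
        if self.n_hubs * self.module_size > self.n_genes:
            raise ValueError("n_hubs * module_size exceeds n_genes")
        if not 0.0 < self.driver_strength < 1.0:
            raise ValueError("driver_strength must be strictly between 0 and 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_expression(spec: HubSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a planted-hub expression matrix and its ground-truth labels.

    Returns
    -------
    expr : ExpressionMatrix
        Genes ``g0001..`` by samples ``s01..``.
    labels : DataFrame
        Columns gene_id, is_hub (0/1), module_id (empty string for
        background genes).
    """
    rng = np.random.default_rng(spec.seed)
    lam = spec.driver_strength**2
    values = np.empty((spec.n_genes, spec.n_samples))
    is_hub = np.zeros(spec.n_genes, dtype=int)
    module_id = [""] * spec.n_genes
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j + 1:02d}" for j in range(spec.n_samples)]

    g = 0
    for h in range(spec.n_hubs):
        driver = rng.standard_normal(spec.n_samples)
        for m in range(spec.module_size):
            loading = np.sqrt(lam)
            if spec.negative_loadings and m % 2 == 1:
                loading = -loading
            eps = rng.standard_normal(spec.n_samples)
            values[g] = spec.noise_sd * (loading * driver + np.sqrt(1 - lam) * eps)
            is_hub[g] = 1
            module_id[g] = f"module{h + 1}"
            g += 1
    while g < spec.n_genes:
        values[g] = spec.noise_sd * rng.standard_normal(spec.n_samples)
        g += 1

    expr = ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)
    labels = pd.DataFrame(
        {"gene_id": gene_ids, "is_hub": is_hub, "module_id": module_id}
    )
    return expr, labels


_SAMPLERS = {
    "uniform": lambda rng, size, p: rng.uniform(
        p.get("low", 0.0), p.get("high", 1.0), size
    ),
    "beta": lambda rng, size, p: rng.beta(p.get("a", 2.0), p.get("b", 2.0), size),
    "normal": lambda rng, size, p: rng.normal(
        p.get("loc", 0.5), p.get("scale", 0.2), size
    ),
    "constant": lambda rng, size, p: np.full(size, float(p.get("value", 0.5))),
}


def generate_random_network(
    n_nodes: int,
    weight_sampler: tuple[str, Mapping[str, Any]] = ("uniform", {}),
    seed: int = 0,
) -> WeightedNetwork:
    """Complete graph on ``n_nodes`` with i.i.d. weights clipped to [0, 1].

    ``weight_sampler`` is ``(name, params)`` with name in {"uniform",
    "beta", "normal", "constant"}.  The constant sampler yields the
    canonical uniform-weight fixture on which every permutation P-value
    equals 1.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    name, params = weight_sampler
    if name not in _SAMPLERS:
        raise ValueError(f"unknown weight sampler {name!r}")
    rng = np.random.default_rng(seed)
    u, v = np.triu_indices(n_nodes, k=1)
    w = np.clip(_SAMPLERS[name](rng, len(u), dict(params)), 0.0, 1.0)
    width = max(3, len(str(n_nodes)))
    nodes = tuple(f"n{i + 1:0{width}d}" for i in range(n_nodes))
    return WeightedNetwork(nodes, u.astype(np.int64), v.astype(np.int64), w)
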