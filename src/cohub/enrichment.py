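"""Fisher-exact over-representation analysis of selected gene sets.

Given a set of genes selected from a network and an annotation map
(term -> genes), each term is tested for over-representation in the
selection with the one-sided hypergeometric tail

    P = sum_{x >= k} C(K, x) C(N - K, n - x) / C(N, n)

where N is the universe size, K the term size within the universe, n the
selection size and k the observed overlap.  The universe should be the
set of genes the selection was drawn from — for a network analysis, the
genes of the network, not the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd
from scipy import stats

from .wnc import bonferroni_adjust

__all__ = ["AnnotationMap", "fisher_enrichment"]


@dataclass(frozen=True)
class AnnotationMap:
    """Term -> gene-set map over a fixed gene universe.

    Every annotated gene must belong to the universe; empty terms are
    rejected.
    """

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "terms",
            {str(t): frozenset(str(g) for g in gs) for t, gs in self.terms.items()},
        )
        object.__setattr__(
            self, "universe", frozenset(str(g) for g in self.universe)
        )
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"annotation term {term!r} has an empty gene set")
            outside = genes - self.universe
            if outside:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    + ", ".join(sorted(outside)[:10])
                )

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "AnnotationMap":
        tdict = {t: frozenset(g) for t, g in terms.items()}
        if universe is None:
            universe = frozenset().union(*tdict.values()) if tdict else frozenset()
        return cls(terms=dict(tdict), universe=frozenset(universe))

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationMap":
        """Intersect every term with a new universe, dropping emptied terms."""
        uni = frozenset(str(g) for g in universe)
        terms = {}
        for t, genes in self.terms.items():
            kept = genes & uni
            if kept:
                terms[t] = kept
        return AnnotationMap(terms=terms, universe=uni)


def fisher_enrichment(
    selected: Iterable[str],
    annot: AnnotationMap,
    correction: Literal["bonferroni", "none"] = "bonferroni",
) -> pd.DataFrame:
    """One-sided over-representation test of ``selected`` against every term.

    Returns a table with columns term_id, k (overlap), K (term size), n
    (selection size), N (universe size), p (hypergeometric upper tail) and
    p_adjusted, sorted by ascending p then term id.
    """
    selected = frozenset(str(g) for g in selected)
    if not selected:
        raise ValueError("the selected gene set is empty")
    outside = selected - annot.universe
    if outside:
        raise ValueError(
            "selected genes outside the annotation universe: "
            + ", ".join(sorted(outside)[:10])
        )
    n_total = len(annot.universe)
    n_sel = len(selected)
    rows = []
    for term, genes in annot.terms.items():
        k = len(genes & selected)
        big_k = len(genes)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_sel))
        p = min(1.0, max(0.0, p))
        rows.append({"term_id": term, "k": k, "K": big_k, "n": n_sel, "N": n_total, "p": p})
    table = pd.DataFrame(rows)
    if correction == "bonferroni":
        adj = bonferroni_adjust(
            dict(zip(table["term_id"], table["p"])), m=len(table)
        )
        table["p_adjusted"] = [adj[t] for t in table["term_id"]]
    elif correction == "none":
        table["p_adjusted"] = table["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table.sort_values(["p", "term_id"]).reset_index(drop=True)
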