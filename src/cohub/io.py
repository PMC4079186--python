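"""Readers and writers for the plain-text formats the tools exchange.

Formats
-------
expression matrix
    TSV; first column gene id, header row of sample ids, float cells.
weighted network
    3-column TSV edge list ``gene1 <TAB> gene2 <TAB> weight``.  SIF input
    (``gene1 <TAB> relation <TAB> gene2``) is accepted only together with
    a fourth weight column or an explicit uniform weight.
binary network
    2-column TSV edge list, or SIF with relation token ``co`` (readable by
    Cytoscape).
gene list
    one gene id per line; blank lines and ``#`` comments ignored.
annotation map
    GMT: ``term <TAB> description <TAB> gene1 <TAB> gene2 ...``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .enrichment import AnnotationMap
from .network import BinaryNetwork, ExpressionMatrix, NetworkError, WeightedNetwork
from .wnc import WncResult

__all__ = [
    "read_expression",
    "write_expression",
    "read_weighted_network",
    "write_weighted_network",
    "read_binary_network",
    "write_binary_network",
    "read_gene_list",
    "read_gmt",
    "write_wnc_table",
    "write_centrality_table",
    "write_enrichment_table",
]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a gene-by-sample expression TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise NetworkError(
            f"{path}: duplicate gene ids: " + ", ".join(map(str, dupes[:10]))
        )
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)]
        raise NetworkError(
            f"{path}: missing expression values for genes: "
            + ", ".join(map(str, bad[:10]))
        )
    return ExpressionMatrix(
        tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(float)
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def _parse_weight(token: str, path: str | Path, lineno: int) -> float:
    try:
        w = float(token)
    except ValueError:
        raise NetworkError(
            f"{path}:{lineno}: malformed edge weight {token!r}"
        ) from None
    if not 0.0 <= w <= 1.0:
        raise NetworkError(f"{path}:{lineno}: edge weight {w} outside [0, 1]")
    return w


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_weighted_network(
    path: str | Path, uniform_weight: float | None = None
) -> WeightedNetwork:
    """Read a weighted edge list (TSV) or a SIF file.

    A SIF line carries ``gene1 relation gene2`` and an optional fourth
    weight column; plain SIF without weights requires ``uniform_weight``.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and len(fields) >= 3 and fields[2].lower() in (
                "weight",
                "w",
            ):
                continue  # header row
            if len(fields) == 3 and _is_number(fields[2]):
                edges.append(
                    (fields[0], fields[1], _parse_weight(fields[2], path, lineno))
                )
            elif len(fields) == 4 and not _is_number(fields[1]):
                edges.append(
                    (fields[0], fields[2], _parse_weight(fields[3], path, lineno))
                )
            elif len(fields) == 3:
                if uniform_weight is None:
                    raise NetworkError(
                        f"{path}:{lineno}: SIF line without a weight column; "
                        "pass a uniform weight to read plain SIF"
                    )
                edges.append((fields[0], fields[2], float(uniform_weight)))
            else:
                raise NetworkError(
                    f"{path}:{lineno}: expected 3 or 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
    if not edges:
        raise NetworkError(f"{path}: no edges found")
    return WeightedNetwork.from_edges(edges)


def write_weighted_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write a 3-column TSV edge list; weights survive a round-trip exactly."""
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tweight\n")
        for a, b, w in net.edge_iter():
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_binary_network(path: str | Path) -> BinaryNetwork:
    """Read a 2-column TSV edge list or a SIF file (3 columns)."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and len(fields) == 2 and fields[0].lower() == "gene1":
                continue
            if len(fields) == 2:
                edges.append((fields[0], fields[1]))
            elif len(fields) == 3:
                edges.append((fields[0], fields[2]))
            else:
                raise NetworkError(
                    f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) fields, "
                    f"got {len(fields)}"
                )
    if not edges:
        raise NetworkError(f"{path}: no edges found")
    return BinaryNetwork.from_edges(edges)


def write_binary_network(
    net: BinaryNetwork, path: str | Path, fmt: str = "tsv"
) -> None:
    """Write 2-column TSV, or SIF with relation token ``co``."""
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("gene1\tgene2\n")
            for a, b in net.edge_iter():
                fh.write(f"{a}\t{b}\n")
        elif fmt == "sif":
            for a, b in net.edge_iter():
                fh.write(f"{a}\tco\t{b}\n")
        else:
            raise ValueError(f"unknown binary-network format {fmt!r}")


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationMap:
    """Read a GMT annotation file; the universe defaults to all annotated genes."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    "at least one gene"
                )
            terms[fields[0]] = {g for g in fields[2:] if g}
    return AnnotationMap.from_terms(terms, universe=universe)


def _fmt_p(p: float) -> str:
    if p != 0 and p < 1e-4:
        return f"{p:.6e}"
    return f"{p:.6g}"


def write_wnc_table(result: WncResult, path: str | Path) -> None:
    """Write the ranked WNC result TSV.

    Scores carry 6 significant digits; P-values below 1e-4 are written in
    scientific notation.
    """
    cols = [
        "gene_id",
        "wnc",
        "wncb",
        "wncc",
        "p_nominal",
        "p_adjusted",
        "rank",
        "significant",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in result.table.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.gene_id),
                        f"{row.wnc:.6g}",
                        f"{row.wncb:.6g}",
                        f"{row.wncc:.6g}",
                        _fmt_p(row.p_nominal),
                        _fmt_p(row.p_adjusted),
                        str(int(row.rank)),
                        str(int(row.significant)),
                    ]
                )
                + "\n"
            )


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
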