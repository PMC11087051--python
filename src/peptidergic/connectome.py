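"""Multilayer peptidergic connectome construction and module analysis.

Cell types are nodes; every (peptide, receptor) pair defines one *layer* of
directed edges from peptide-expressing to receptor-expressing cell types
(self-edges allowed — autocrine signaling). The edge weight combines
expression and pharmacological sensitivity::

    weight = sqrt(PeptideExpr * ReceptorExpr) * |log10(EC50 [M])|

i.e. the geometric mean of the two expression levels weighted by the
absolute decadic log of the EC50. Zero-weight edges are excluded.

Modules are detected with the Leiden algorithm on the weight-collapsed
undirected projection (parallel layer edges summed); hub cell types are
ranked by total incident strength.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import igraph as ig
import leidenalg as la
import networkx as nx
import pandas as pd

__all__ = [
    "edge_weight",
    "build_network",
    "detect_modules",
    "hub_scores",
    "write_gexf",
]


def edge_weight(pexpr: float, rexpr: float, ec50: float) -> float:
    """sqrt(PeptideExpr * ReceptorExpr) * |log10(EC50 in M)|."""
    if pexpr < 0 or rexpr < 0:
        raise ValueError("expression values must be >= 0")
    if ec50 <= 0:
        raise ValueError("EC50 must be strictly positive (molar)")
    return math.sqrt(pexpr * rexpr) * abs(math.log10(ec50))


def _pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        df = pairs.rename(columns={"ec50_M": "ec50"})
        return df[["peptide", "receptor", "ec50"]]
    return pd.DataFrame(pairs, columns=["peptide", "receptor", "ec50"])


def build_network(
    expr: pd.DataFrame,
    pairs,
    expr_floor: float = 0.0,
) -> nx.MultiDiGraph:
    """Assemble the multilayer connectome graph.

    Parameters
    ----------
    expr
        Cell-type x gene average-expression table (rows: cell types,
        columns: peptide precursors and receptors, values >= 0).
    pairs
        (peptide, receptor, ec50) triples — list of tuples or a DataFrame
        with those columns (``ec50_M`` accepted as alias).
    expr_floor
        Both endpoint expressions must be strictly greater than this for an
        edge to be created (default 0: any positive expression connects).

    Pairs whose genes are missing from the table are skipped with a warning
    and listed in ``graph.graph["skipped_pairs"]``.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression table contains negative values")
    pf = _pairs_frame(pairs)
    g = nx.MultiDiGraph()
    g.add_nodes_from(expr.index)
    skipped: list[tuple[str, str]] = []
    for row in pf.itertuples(index=False):
        pep, rec, ec50 = row.peptide, row.receptor, float(row.ec50)
        if pep not in expr.columns or rec not in expr.columns:
            skipped.append((pep, rec))
            continue
        layer = f"{pep}|{rec}"
        pcol, rcol = expr[pep], expr[rec]
        for src in expr.index:
            pe = float(pcol[src])
            if pe <= expr_floor:
                continue
            for tgt in expr.index:
                re_ = float(rcol[tgt])
                if re_ <= expr_floor:
                    continue
                w = edge_weight(pe, re_, ec50)
                if w <= 0:
                    continue
                g.add_edge(
                    src, tgt, key=layer,
                    weight=w, peptide=pep, receptor=rec, layer=layer, ec50=ec50,
                )
    if skipped:
        warnings.warn(f"skipped pairs with missing genes: {skipped}", stacklevel=2)
    g.graph["skipped_pairs"] = skipped
    return g


def detect_modules(
    graph: nx.MultiDiGraph, resolution: float = 1.0, seed: int = 42
) -> dict[str, int]:
    """Leiden partition of the weight-collapsed undirected projection.

    Parallel and antiparallel edges are summed into a single undirected
    weight per node pair (self-loops dropped for the partition). The result
    is deterministic for a fixed seed. Nodes without any edge each get
    their own singleton module (with a warning when the whole graph is
    edgeless).
    """
    collapsed: dict[tuple[str, str], float] = {}
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        key = (u, v) if str(u) <= str(v) else (v, u)
        collapsed[key] = collapsed.get(key, 0.0) + float(data.get("weight", 1.0))

    nodes = list(graph.nodes)
    if not collapsed:
        warnings.warn("edgeless graph: every node is its own module", stacklevel=2)
        return {n: i for i, n in enumerate(nodes)}

    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in collapsed]
    weights = list(collapsed.values())
    igg = ig.Graph(n=len(nodes), edges=edges)
    part = la.find_partition(
        igg,
        la.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = dict(zip(nodes, part.membership))

    # isolated nodes: give each its own fresh module id
    next_id = max(membership.values()) + 1
    degree = igg.degree()
    for n in nodes:
        if degree[index[n]] == 0:
            membership[n] = next_id
            next_id += 1
    graph.graph["modules"] = membership
    graph.graph["resolution"] = resolution
    graph.graph["seed"] = seed
    return membership


def hub_scores(graph: nx.MultiDiGraph) -> pd.DataFrame:
    """Rank cell types by total incident edge strength.

    Columns: in_strength, out_strength, total_strength, rank (1 = strongest
    hub). Self-loops count toward both in- and out-strength.
    """
    ins = dict.fromkeys(graph.nodes, 0.0)
    outs = dict.fromkeys(graph.nodes, 0.0)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        outs[u] += w
        ins[v] += w
    df = pd.DataFrame(
        {
            "cell_type": list(graph.nodes),
            "in_strength": [ins[n] for n in graph.nodes],
            "out_strength": [outs[n] for n in graph.nodes],
        }
    )
    df["total_strength"] = df["in_strength"] + df["out_strength"]
    df = df.sort_values(
        ["total_strength", "cell_type"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def write_gexf(graph: nx.MultiDiGraph, path) -> None:
    """Serialize the connectome to GEXF (Gephi-readable)."""
    nx.write_gexf(graph, path)
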