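"""Interaction networks over differential-expression target genes.

Genes upregulated in a tumor subset (p below threshold and log2FC above 1.5,
both strict) are projected onto a user-supplied pairwise interaction table
(a STRING-export-like edge list with an aggregate interaction score per gene
pair), and the induced subgraph's connectivity is summarised as edges/node
(the literal edge-to-node ratio; mean degree 2E/N is available as a switch)
and the total connection score (sum of retained edge scores).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

EDGE_COLUMNS = ["gene_a", "gene_b", "score"]


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    edges_per_node: float
    total_connection_score: float
    empty: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def select_nodes(
    de: pd.DataFrame,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.5,
    p_column: str = "p_adj",
) -> set:
    """Target genes for the string map: p < threshold and log2fc > threshold.

    The fold-change filter is directional (upregulated in the focal group)
    and strict on both inequalities, so a gene at exactly log2fc = 1.5 is
    excluded.
    """
    if p_column not in de.columns:
        raise ValueError(f"DE table has no column {p_column!r}")
    mask = (de[p_column] < p_threshold) & (de["log2fc"] > lfc_threshold)
    return set(de.index[mask])


def dedupe_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize an undirected edge table: drop self-loops, orient each
    pair lexicographically and keep the highest-score duplicate."""
    e = edges[EDGE_COLUMNS].copy()
    e = e[e["gene_a"] != e["gene_b"]]
    lo = e[["gene_a", "gene_b"]].min(axis=1)
    hi = e[["gene_a", "gene_b"]].max(axis=1)
    e["gene_a"], e["gene_b"] = lo, hi
    e = (
        e.sort_values("score", ascending=False)
        .drop_duplicates(["gene_a", "gene_b"])
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
    return e


def build_network(
    nodes: set,
    edges: pd.DataFrame,
    min_score: float = 0.4,
) -> nx.Graph:
    """Induced interaction subgraph on the selected genes.

    Edges are kept when both endpoints are selected and the interaction
    score is at least ``min_score``; selected genes without any retained
    interaction stay in the graph as isolated nodes.  The number of edges
    dropped for referencing unselected genes is recorded in
    ``graph.graph["dropped_edges"]``.
    """
    e = dedupe_edges(edges)
    g = nx.Graph(min_score=min_score)
    g.add_nodes_from(sorted(nodes))
    in_nodes = e["gene_a"].isin(nodes) & e["gene_b"].isin(nodes)
    strong = e["score"] >= min_score
    kept = e[in_nodes & strong]
    g.add_weighted_edges_from(
        kept.itertuples(index=False, name=None), weight="score"
    )
    g.graph["dropped_edges"] = int((~in_nodes).sum())
    return g


def connectivity_stats(graph: nx.Graph, mode: str = "ratio") -> NetworkStats:
    """Connectivity summary of a target network.

    ``mode='ratio'`` reports edges/node as E/N (the literal reading);
    ``mode='mean_degree'`` reports 2E/N.  An empty graph yields all-zero
    stats with the ``empty`` flag set.
    """
    if mode not in ("ratio", "mean_degree"):
        raise ValueError(f"unknown edges-per-node mode: {mode!r}")
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    if n == 0:
        return NetworkStats(0, 0, 0.0, 0.0, empty=True)
    per_node = m / n if mode == "ratio" else 2 * m / n
    total = float(
        np.sum([d.get("score", 0.0) for _, _, d in graph.edges(data=True)])
    )
    return NetworkStats(n, m, float(per_node), total)


def export_edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Graph back to a canonical 3-column edge table (for TSV export)."""
    rows = [
        {"gene_a": min(a, b), "gene_b": max(a, b), "score": d.get("score", np.nan)}
        for a, b, d in graph.edges(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=EDGE_COLUMNS)
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
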