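"""Protein-interaction network topology and composite hub ranking.

Graphs come from confidence-weighted edge lists (STRING-style); only
edges with confidence strictly above the configured threshold are kept.
Three per-node centralities are computed on the unweighted graph:

* degree - incident edge count;
* betweenness - unnormalized shortest-path betweenness, summed over
  unordered source/target pairs;
* closeness - harmonic centrality, sum over other nodes of the
  reciprocal shortest-path distance (0 for unreachable nodes), robust
  to the disconnected graphs that high-confidence interaction subsets
  commonly are.  Classic closeness is available as an alternative.

Each metric is z-standardized across the analyzed graph's nodes using
the sample standard deviation (ddof=1, z = 0 when the metric is
constant), and the composite hub score is the sum of the three
z-scores.  Ranking is by composite descending, ties broken by node id.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError

logger = logging.getLogger(__name__)


def build_graph(
    edges: pd.DataFrame,
    confidence_min: float = 0.9,
    nodes: Iterable | None = None,
) -> nx.Graph:
    """Build an undirected graph from a ``u, v, confidence`` edge list.

    Self-loops are dropped (logged); duplicate undirected pairs collapse
    to their maximum confidence; edges are kept iff
    ``confidence > confidence_min`` (strict).  ``nodes`` is an optional
    roster whose members are retained even when isolated.
    """
    required = {"u", "v", "confidence"}
    if not required <= set(edges.columns):
        raise ParseError(f"edge list needs columns {sorted(required)}")
    conf = edges["confidence"].astype(float)
    bad = ~((conf >= 0) & (conf <= 1))
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"edge row {edges.index[idx]}: confidence {conf.iloc[idx]} outside [0, 1]"
        )
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    n_loops = 0
    for u, v, c in zip(edges["u"], edges["v"], conf):
        if u == v:
            n_loops += 1
            continue
        if graph.has_edge(u, v):
            graph[u][v]["confidence"] = max(graph[u][v]["confidence"], c)
        else:
            graph.add_edge(u, v, confidence=c)
    if n_loops:
        logger.info("build_graph: dropped %d self-loop(s)", n_loops)
    drop = [
        (u, v) for u, v, c in graph.edges(data="confidence") if not c > confidence_min
    ]
    graph.remove_edges_from(drop)
    if nodes is None:
        graph.remove_nodes_from([n for n in list(graph) if graph.degree(n) == 0])
    return graph


def centralities(graph: nx.Graph, closeness: str = "harmonic") -> pd.DataFrame:
    """Degree, betweenness and closeness for every node.

    Returns a DataFrame with columns ``node, degree, betweenness,
    closeness`` sorted by node id; z-score columns are left to
    :func:`composite_score`.
    """
    if graph.number_of_nodes() == 0:
        raise ParameterError("cannot compute centralities of an empty graph")
    if closeness not in ("harmonic", "classic"):
        raise ParameterError(f"unknown closeness variant: {closeness!r}")
    betw = nx.betweenness_centrality(graph, normalized=False)
    if closeness == "harmonic":
        close = nx.harmonic_centrality(graph)
    else:
        close = nx.closeness_centrality(graph)
    records = [
        {
            "node": node,
            "degree": graph.degree(node),
            "betweenness": betw[node],
            "closeness": close[node],
        }
        for node in graph
    ]
    return (
        pd.DataFrame(records)
        .sort_values("node", key=lambda s: s.astype(str))
        .reset_index(drop=True)
    )


def _zscore(values: np.ndarray) -> np.ndarray:
    # Sample SD (ddof=1); a constant metric carries no ranking
    # information, so its z-scores are defined as 0.
    if values.size < 2:
        return np.zeros_like(values, dtype=float)
    sd = values.std(ddof=1)
    # Guard against float jitter in an effectively constant metric
    # (e.g. accumulated betweenness on a vertex-transitive graph).
    if sd <= 1e-12 * max(1.0, float(np.abs(values).max())):
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def composite_score(records: pd.DataFrame) -> pd.DataFrame:
    """Standardize the three centralities and rank by their sum.

    Adds ``z_degree, z_betweenness, z_closeness, composite`` and returns
    rows sorted by composite descending, node id ascending on ties.
    """
    if len(records) == 0:
        raise ParameterError("no centrality records to score")
    out = records.copy()
    for metric in ("degree", "betweenness", "closeness"):
        out[f"z_{metric}"] = _zscore(out[metric].to_numpy(dtype=float))
    out["composite"] = out["z_degree"] + out["z_betweenness"] + out["z_closeness"]
    out["_node_key"] = out["node"].astype(str)
    out = (
        out.sort_values(["composite", "_node_key"], ascending=[False, True])
        .drop(columns="_node_key")
        .reset_index(drop=True)
    )
    return out


def top_k_targets(ranked: pd.DataFrame, k: int) -> list:
    """First ``k`` nodes of a :func:`composite_score` ranking."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return ranked["node"].head(k).tolist()


def subnetwork_by_genes(graph: nx.Graph, genes: Iterable) -> nx.Graph:
    """Induced subgraph on the intersection of graph nodes and ``genes``."""
    keep = set(genes) & set(graph.nodes)
    if not keep:
        logger.warning("subnetwork_by_genes: gene set disjoint from graph")
    return graph.subgraph(keep).copy()
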