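"""Interaction-network centralities against a brute-force oracle."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wsyrnet.errors import ParameterError, ParseError
from wsyrnet.ppin import (
    build_graph,
    centralities,
    composite_score,
    subnetwork_by_genes,
    top_k_targets,
)
from wsyrnet.synthetic import gen_ppi_graph


def edges_frame(pairs, confidence=0.95):
    return pd.DataFrame(
        [{"u": u, "v": v, "confidence": confidence} for u, v in pairs]
    )


def brute_force_centralities(graph):
    """Independent oracle: BFS distances plus exhaustive enumeration of
    shortest paths by depth-limited search."""
    nodes = sorted(graph.nodes, key=str)
    dist = {
        s: nx.single_source_shortest_path_length(graph, s) for s in nodes
    }

    def all_shortest_paths(s, t):
        d = dist[s].get(t)
        if d is None:
            return []
        paths = []

        def walk(path):
            head = path[-1]
            if head == t:
                paths.append(list(path))
                return
            if len(path) - 1 == d:
                return
            for nxt in graph.neighbors(head):
                if nxt not in path and dist[s].get(nxt) == len(path):
                    walk(path + [nxt])

        walk([s])
        return paths

    out = {}
    for v in nodes:
        degree = graph.degree(v)
        closeness = sum(
            1.0 / d for t, d in dist[v].items() if t != v and d > 0
        )
        betweenness = 0.0
        for s, t in itertools.combinations([n for n in nodes if n != v], 2):
            paths = all_shortest_paths(s, t)
            if paths:
                betweenness += sum(v in p for p in paths) / len(paths)
        out[v] = (degree, betweenness, closeness)
    return out


def assert_matches_oracle(graph):
    oracle = brute_force_centralities(graph)
    table = centralities(graph).set_index("node")
    for node, (deg, betw, close) in oracle.items():
        assert table.loc[node, "degree"] == deg
        assert table.loc[node, "betweenness"] == pytest.approx(betw, abs=1e-9)
        assert table.loc[node, "closeness"] == pytest.approx(close, abs=1e-9)


class TestBuildGraph:
    def test_strict_confidence_threshold(self):
        edges = pd.DataFrame(
            {"u": ["a", "c", "e"], "v": ["b", "d", "f"],
             "confidence": [0.95, 0.90, 0.41]}
        )
        graph = build_graph(edges, confidence_min=0.9)
        assert graph.number_of_edges() == 1
        assert graph.has_edge("a", "b")

    def test_zero_threshold_keeps_all(self):
        edges = edges_frame([("a", "b"), ("b", "c")], confidence=0.5)
        assert build_graph(edges, 0.0).number_of_edges() == 2

    def test_generator_edge_count_bookkeeping(self):
        edges, truth = gen_ppi_graph(30, 2, 3, seed=11)
        graph = build_graph(edges, 0.0)
        assert graph.number_of_edges() == truth.n_edges

    def test_confidence_out_of_range_rejected(self):
        edges = edges_frame([("a", "b")], confidence=1.5)
        with pytest.raises(ParseError):
            build_graph(edges, 0.5)

    def test_duplicates_collapse_to_max(self):
        edges = pd.DataFrame(
            {"u": ["a", "b"], "v": ["b", "a"], "confidence": [0.3, 0.95]}
        )
        graph = build_graph(edges, 0.5)
        assert graph["a"]["b"]["confidence"] == 0.95

    def test_roster_keeps_isolated_nodes(self):
        edges = edges_frame([("a", "b")])
        graph = build_graph(edges, 0.5, nodes=["a", "b", "z"])
        assert "z" in graph


class TestCentralities:
    def test_star_hand_enumeration(self):
        graph = build_graph(edges_frame([("c", "a"), ("c", "b"), ("c", "d")]), 0.5)
        table = centralities(graph).set_index("node")
        assert tuple(table.loc["c"][["degree", "betweenness", "closeness"]]) == (3, 3.0, 3.0)
        for leaf in "abd":
            assert tuple(table.loc[leaf][["degree", "betweenness", "closeness"]]) == (1, 0.0, 2.0)

    def test_single_edge(self):
        graph = build_graph(edges_frame([("a", "b")]), 0.5)
        table = centralities(graph).set_index("node")
        assert (table["degree"] == 1).all()
        assert (table["betweenness"] == 0).all()
        assert (table["closeness"] == 1.0).all()

    def test_empty_graph_rejected(self):
        with pytest.raises(ParameterError):
            centralities(nx.Graph())

    @pytest.mark.parametrize("n,p,seed", [
        (4, 0.5, 0), (5, 0.4, 1), (6, 0.5, 2), (7, 0.3, 3), (8, 0.35, 4),
        (8, 0.6, 5), (6, 0.2, 6),  # sparse ones are usually disconnected
    ])
    def test_random_graphs_match_oracle(self, n, p, seed):
        graph = nx.gnp_random_graph(n, p, seed=seed)
        graph.add_node("iso")  # always include one isolated node
        assert_matches_oracle(graph)

    @pytest.mark.parametrize(
        "maker", [nx.path_graph, nx.cycle_graph, nx.complete_graph],
        ids=["path", "cycle", "complete"],
    )
    def test_canonical_graphs_match_oracle(self, maker):
        assert_matches_oracle(maker(6))


class TestCompositeScore:
    def test_cycle_is_degenerate_tie(self):
        ranked = composite_score(centralities(nx.cycle_graph(6)))
        assert ranked["composite"].abs().max() == 0.0

    def test_star_hand_values(self):
        graph = build_graph(edges_frame([("c", "a"), ("c", "b"), ("c", "d")]), 0.5)
        ranked = composite_score(centralities(graph)).set_index("node")
        assert ranked.loc["c", "composite"] == pytest.approx(4.5)
        for leaf in "abd":
            assert ranked.loc[leaf, "composite"] == pytest.approx(-1.5)

    def test_composite_is_sum_of_z(self):
        edges, _ = gen_ppi_graph(25, 2, 3, seed=4)
        ranked = composite_score(centralities(build_graph(edges, 0.0)))
        assert np.allclose(
            ranked["composite"],
            ranked["z_degree"] + ranked["z_betweenness"] + ranked["z_closeness"],
        )

    def test_shift_invariance(self):
        edges, _ = gen_ppi_graph(20, 1, 3, seed=8)
        records = centralities(build_graph(edges, 0.0))
        shifted = records.copy()
        for metric in ("degree", "betweenness", "closeness"):
            shifted[metric] = shifted[metric] + 7.0
        assert np.allclose(
            composite_score(records)["composite"],
            composite_score(shifted)["composite"],
        )

    def test_planted_hubs_rank_top(self):
        edges, truth = gen_ppi_graph(50, 3, 4, seed=7)
        ranked = composite_score(centralities(build_graph(edges, 0.0)))
        assert set(top_k_targets(ranked, 3)) == set(truth.hub_ids)

    def test_unhubbed_spread_much_smaller(self):
        def spread(n_hubs, seed):
            edges, _ = gen_ppi_graph(50, n_hubs, 4, seed=seed)
            ranked = composite_score(centralities(build_graph(edges, 0.0)))
            return ranked["composite"].max() - ranked["composite"].min()

        assert spread(0, 13) < spread(3, 13)


class TestTopKAndSubnetwork:
    def test_k_larger_than_graph_returns_all(self):
        ranked = composite_score(centralities(nx.path_graph(4)))
        assert len(top_k_targets(ranked, 99)) == 4

    def test_k_one_on_star_is_center(self):
        graph = build_graph(edges_frame([("c", "a"), ("c", "b"), ("c", "d")]), 0.5)
        ranked = composite_score(centralities(graph))
        assert top_k_targets(ranked, 1) == ["c"]

    def test_subnetwork_identity_and_disjoint(self):
        edges, _ = gen_ppi_graph(20, 0, 3, seed=5)
        graph = build_graph(edges, 0.0)
        same = subnetwork_by_genes(graph, set(graph.nodes))
        assert nx.utils.graphs_equal(graph, same)
        assert subnetwork_by_genes(graph, {"nope"}).number_of_nodes() == 0

    def test_subnetwork_matches_edge_filter(self):
        edges, _ = gen_ppi_graph(30, 0, 4, seed=6)
        graph = build_graph(edges, 0.0)
        keep = set(sorted(graph.nodes)[::2])
        sub = subnetwork_by_genes(graph, keep)
        expected = {
            frozenset((u, v)) for u, v in graph.edges if u in keep and v in keep
        }
        assert {frozenset(e) for e in sub.edges} == expected
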