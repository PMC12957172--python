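"""Network construction and topology metrics, with BFS and dense
power-iteration oracles."""

import numpy as np
import pytest

from morbnet.errors import DataError
from morbnet.network import (
    build_network,
    harmonic_centrality,
    node_metrics,
    pagerank,
    pagerank_hubs,
    summarize_network,
    system_aggregates,
)


def net_from(edges, nodes=None, label="g"):
    if nodes is None:
        nodes = sorted({n for u, v, _ in edges for n in (u, v)})
    return build_network(nodes, edges, label=label)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def bfs_distances(adj, start):
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def harmonic_oracle(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v, _ in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v) / (n - 1)
    return out


def pagerank_oracle(nodes, edges, damping=0.85, steps=100):
    """Dense power iteration on the weighted transition matrix; dangling
    nodes redistribute uniformly."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, wt in edges:
        w[idx[u], idx[v]] += wt
        w[idx[v], idx[u]] += wt
    out_strength = w.sum(axis=1)
    p = np.full(n, 1.0 / n)
    for _ in range(steps):
        nxt = np.full(n, (1 - damping) / n)
        for i in range(n):
            if out_strength[i] == 0:
                nxt += damping * p[i] / n
            else:
                nxt += damping * p[i] * w[i] / out_strength[i]
        p = nxt
    return {v: p[idx[v]] for v in nodes}


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

def test_empty_edge_list_keeps_isolated_nodes():
    net = net_from([], nodes=["a", "b", "c"])
    assert net.nodes == ["a", "b", "c"]
    assert net.edges == []


def test_duplicate_edge_rejected():
    with pytest.raises(DataError, match="duplicate edge"):
        net_from([("a", "b", 0.5), ("b", "a", 0.4)])


def test_unknown_node_and_self_loop_rejected():
    with pytest.raises(DataError, match="unknown node"):
        build_network(["a", "b"], [("a", "z", 0.5)])
    with pytest.raises(DataError, match="self-loop"):
        build_network(["a"], [("a", "a", 0.5)])


def test_weight_outside_unit_interval_rejected():
    with pytest.raises(DataError, match="weight"):
        net_from([("a", "b", 1.5)])
    with pytest.raises(DataError, match="weight"):
        net_from([("a", "b", 0.0)])


def test_adjacency_matches_hand_built_matrix():
    edges = [("a", "b", 0.2), ("a", "c", 0.4), ("b", "c", 0.1), ("d", "e", 0.9)]
    net = net_from(edges, nodes=list("abcde"))
    expected = {
        ("a", "b"): 0.2, ("a", "c"): 0.4, ("b", "c"): 0.1, ("d", "e"): 0.9,
    }
    assert {(u, v): w for u, v, w in net.edges} == expected
    assert net.graph.degree("a") == 2
    assert net.graph.degree("e") == 1


# --------------------------------------------------------------------------
# whole-network summaries (worked examples with published metric layouts)
# --------------------------------------------------------------------------

def random_network(rng, n_nodes, n_edges):
    nodes = [f"n{i}" for i in range(n_nodes)]
    possible = [
        (nodes[i], nodes[j]) for i in range(n_nodes) for j in range(i + 1, n_nodes)
    ]
    chosen = rng.choice(len(possible), size=n_edges, replace=False)
    edges = [
        (*possible[k], float(rng.uniform(0.05, 1.0))) for k in sorted(chosen)
    ]
    return build_network(nodes, edges)


@pytest.mark.parametrize(
    "n_nodes, n_edges, density, avg_degree",
    [
        (22, 82, 0.355, 7.455),   # male T1DM network scale
        (22, 92, 0.398, 8.364),   # female T1DM
        (22, 78, 0.338, 7.091),   # male T2DM
        (20, 89, 0.468, 8.900),   # female T2DM
    ],
)
def test_density_and_average_degree_from_counts(n_nodes, n_edges, density, avg_degree):
    """Any simple graph with these node/edge counts reproduces the published
    density and average degree to 3 decimals."""
    rng = np.random.default_rng(n_nodes * 1000 + n_edges)
    net = random_network(rng, n_nodes, n_edges)
    s = summarize_network(net)
    assert round(s.density, 3) == density
    assert round(s.avg_degree, 3) == avg_degree


def test_complete_graph_density_one():
    nodes = list("abcde")
    edges = [
        (u, v, 0.5) for i, u in enumerate(nodes) for v in nodes[i + 1:]
    ]
    s = summarize_network(net_from(edges, nodes=nodes))
    assert s.density == pytest.approx(1.0)


def test_density_undefined_below_two_nodes():
    with pytest.raises(DataError, match="density"):
        summarize_network(build_network(["a"], []))


def test_handshake_identities():
    rng = np.random.default_rng(17)
    net = random_network(rng, 12, 30)
    g = net.graph
    assert sum(dict(g.degree()).values()) == 2 * g.number_of_edges()
    total_w = sum(w for _, _, w in net.edges)
    assert sum(
        g.degree(v, weight="weight") for v in g.nodes
    ) == pytest.approx(2 * total_w)
    s = summarize_network(net)
    assert s.avg_degree == pytest.approx(2 * s.n_edges / s.n_nodes)
    assert s.avg_weighted_degree == pytest.approx(2 * total_w / s.n_nodes)


# --------------------------------------------------------------------------
# harmonic centrality
# --------------------------------------------------------------------------

def test_star_center_has_unit_harmonic_centrality():
    edges = [("hub", f"s{i}", 0.5) for i in range(4)]
    h = harmonic_centrality(net_from(edges))
    assert h["hub"] == pytest.approx(1.0)


def test_isolated_node_has_zero_harmonic_centrality():
    net = net_from([("a", "b", 0.5)], nodes=["a", "b", "iso"])
    h = harmonic_centrality(net)
    assert h["iso"] == 0.0


def test_path_graph_harmonic_value():
    h = harmonic_centrality(net_from([("a", "b", 0.5), ("b", "c", 0.5)]))
    assert h["a"] == pytest.approx((1 + 0.5) / 2)   # = 0.75
    assert h["b"] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_harmonic_matches_bfs_oracle_and_unit_range(seed):
    rng = np.random.default_rng(seed)
    net = random_network(rng, 10, int(rng.integers(5, 20)))
    h = harmonic_centrality(net)
    oracle = harmonic_oracle(net.nodes, net.edges)
    for v in net.nodes:
        assert h[v] == pytest.approx(oracle[v], abs=1e-12)
        assert 0.0 <= h[v] <= 1.0


# --------------------------------------------------------------------------
# PageRank
# --------------------------------------------------------------------------

def test_pagerank_uniform_on_cycle():
    nodes = [f"n{i}" for i in range(6)]
    edges = [(nodes[i], nodes[(i + 1) % 6], 0.5) for i in range(6)]
    pr = pagerank(net_from(edges, nodes=nodes))
    for v in nodes:
        assert pr[v] == pytest.approx(1 / 6, abs=1e-9)


def test_pagerank_sums_to_one_with_isolates():
    net = net_from(
        [("a", "b", 0.3), ("b", "c", 0.9)], nodes=["a", "b", "c", "iso1", "iso2"]
    )
    pr = pagerank(net)
    assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)


def test_pagerank_matches_dense_power_iteration_oracle():
    edges = [("a", "b", 0.9), ("a", "c", 0.1), ("b", "c", 0.5), ("c", "d", 0.2)]
    net = net_from(edges)
    pr = pagerank(net)
    oracle = pagerank_oracle(net.nodes, edges)
    for v in net.nodes:
        assert pr[v] == pytest.approx(oracle[v], abs=1e-8)


def test_pagerank_independent_of_node_insertion_order():
    edges = [("a", "b", 0.9), ("b", "c", 0.5), ("c", "d", 0.2)]
    pr1 = pagerank(build_network(["a", "b", "c", "d"], edges))
    pr2 = pagerank(build_network(["d", "c", "b", "a"], edges))
    for v in "abcd":
        assert pr1[v] == pytest.approx(pr2[v], abs=1e-12)


def test_hub_ranking_top_k_with_lexicographic_ties():
    # two symmetric leaves tie exactly: lexicographic order decides
    edges = [("hub", "a", 0.5), ("hub", "b", 0.5)]
    hubs = pagerank_hubs(net_from(edges), k=2)
    assert hubs[0][0] == "hub"
    assert hubs[1][0] == "a"


def test_node_metrics_table_is_consistent():
    rng = np.random.default_rng(3)
    net = random_network(rng, 8, 12)
    nm = node_metrics(net).set_index("code")
    assert nm["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
    for v in net.nodes:
        assert nm.loc[v, "degree"] == net.graph.degree(v)


# --------------------------------------------------------------------------
# system-level aggregates
# --------------------------------------------------------------------------

def test_single_chapter_totals_equal_twice_edge_count():
    edges = [("a", "b", 0.5), ("b", "c", 0.5)]
    net = net_from(edges)
    agg = system_aggregates(net, {"a": "IX", "b": "IX", "c": "IX"})
    assert len(agg) == 1
    assert agg.iloc[0]["total_degree"] == 2 * 2


def test_two_chapter_totals_match_hand_summation():
    edges = [("a", "b", 0.4), ("a", "c", 0.6), ("c", "d", 0.2)]
    net = net_from(edges)
    chapters = {"a": "IX", "b": "IX", "c": "XI", "d": "XI"}
    agg = system_aggregates(net, chapters).set_index("chapter")
    # hand summation: a deg2 + b deg1 = 3 for IX; c deg2 + d deg1 = 3 for XI
    assert agg.loc["IX", "total_degree"] == 3
    assert agg.loc["XI", "total_degree"] == 3
    assert agg.loc["IX", "total_weighted_degree"] == pytest.approx(0.4 + 0.6 + 0.4)
    assert agg.loc["XI", "total_weighted_degree"] == pytest.approx(0.6 + 0.2 + 0.2)


def test_unmapped_node_raises():
    net = net_from([("a", "b", 0.5)])
    with pytest.raises(DataError, match="chapter"):
        system_aggregates(net, {"a": "IX"})
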