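"""Multimorbidity networks and their topology metrics.

Each subgroup's network is a simple weighted undirected graph: nodes are the
cohort's retained comorbid conditions (isolated conditions stay in the node
set), edges are the significant co-occurring pairs with SCI weights in
(0, 1].  Reported metrics:

* degree — direct connections per node;
* weighted degree — sum of incident SCI weights;
* density — observed edges over the maximum possible;
* harmonic centrality — mean inverse shortest-path (hop-count) distance to
  all other nodes, with unreachable pairs contributing 0; normalized by
  (n - 1) so values lie in [0, 1] and are usable on disconnected graphs;
* PageRank (damping 0.85 on the SCI-weighted graph) — hub diseases are the
  top-k conditions by PageRank.

SCI weights influence weighted degree and PageRank only; path-based
centrality uses unweighted hop counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class MultimorbidityNetwork:
    """A subgroup's disease co-occurrence graph."""

    label: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self.graph.edges(data=True)
        )

    @property
    def edge_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((min(u, v), max(u, v)) for u, v in self.graph.edges)


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network metrics, one row of the summary table."""

    label: str
    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    avg_weighted_degree: float
    avg_harmonic_centrality: float


def build_network(
    nodes: Sequence[str],
    edges: Sequence[tuple[str, str, float]],
    label: str = "",
) -> MultimorbidityNetwork:
    """Assemble a simple weighted undirected graph; validates its invariants."""
    g = nx.Graph()
    node_set = set(nodes)
    if len(node_set) != len(nodes):
        raise DataError(f"network {label}: duplicate nodes")
    g.add_nodes_from(sorted(node_set))
    seen = set()
    for u, v, w in edges:
        if u not in node_set or v not in node_set:
            raise DataError(f"network {label}: edge ({u}, {v}) references unknown node")
        if u == v:
            raise DataError(f"network {label}: self-loop at {u}")
        key = (min(u, v), max(u, v))
        if key in seen:
            raise DataError(f"network {label}: duplicate edge {key}")
        seen.add(key)
        if not 0.0 < w <= 1.0:
            raise DataError(f"network {label}: edge weight {w} outside (0, 1]")
        g.add_edge(*key, weight=float(w))
    return MultimorbidityNetwork(label=label, graph=g)


def harmonic_centrality(net: MultimorbidityNetwork) -> dict[str, float]:
    """Normalized harmonic centrality per node (hop-count shortest paths)."""
    n = net.graph.number_of_nodes()
    if n < 2:
        raise DataError("harmonic centrality needs at least 2 nodes")
    raw = nx.harmonic_centrality(net.graph)  # sum of 1/d over reachable nodes
    return {node: raw[node] / (n - 1) for node in net.graph.nodes}


def pagerank(
    net: MultimorbidityNetwork, damping: float = 0.85
) -> dict[str, float]:
    """PageRank on the SCI-weighted graph (isolated nodes dangle uniformly)."""
    return nx.pagerank(
        net.graph, alpha=damping, weight="weight", tol=1e-12, max_iter=1000
    )


def pagerank_hubs(
    net: MultimorbidityNetwork, k: int = 10, damping: float = 0.85
) -> list[tuple[str, float]]:
    """Top-k hub diseases by PageRank; ties broken lexicographically."""
    scores = pagerank(net, damping=damping)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def node_metrics(
    net: MultimorbidityNetwork, damping: float = 0.85
) -> pd.DataFrame:
    """Per-node metric table: degree, weighted degree, harmonic centrality, PageRank."""
    g = net.graph
    harm = harmonic_centrality(net)
    pr = pagerank(net, damping=damping)
    rows = [
        {
            "code": v,
            "degree": g.degree(v),
            "weighted_degree": g.degree(v, weight="weight"),
            "harmonic_centrality": harm[v],
            "pagerank": pr[v],
        }
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows)


def summarize_network(net: MultimorbidityNetwork) -> NetworkSummary:
    """Whole-network metrics; density is undefined below two nodes."""
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise DataError(f"network {net.label}: density undefined for n_nodes < 2")
    total_weight = sum(d["weight"] for _, _, d in g.edges(data=True))
    harm = harmonic_centrality(net)
    return NetworkSummary(
        label=net.label,
        n_nodes=n,
        n_edges=m,
        density=m / (n * (n - 1) / 2),
        avg_degree=2 * m / n,
        avg_weighted_degree=2 * total_weight / n,
        avg_harmonic_centrality=sum(harm.values()) / n,
    )


def system_aggregates(
    net: MultimorbidityNetwork, chapter_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-ICD-chapter totals of degree and weighted degree.

    Chapters with no member nodes are absent; rows sorted by total degree
    descending (ties by chapter label).  Every node must be mapped.
    """
    g = net.graph
    unmapped = sorted(set(g.nodes) - set(chapter_map))
    if unmapped:
        raise DataError(f"nodes without an ICD-10 chapter: {unmapped}")
    totals: dict[str, dict[str, float]] = {}
    for v in g.nodes:
        ch = chapter_map[v]
        t = totals.setdefault(ch, {"total_degree": 0, "total_weighted_degree": 0.0})
        t["total_degree"] += g.degree(v)
        t["total_weighted_degree"] += g.degree(v, weight="weight")
    rows = [
        {"chapter": ch, **vals}
        for ch, vals in sorted(
            totals.items(), key=lambda kv: (-kv[1]["total_degree"], kv[0])
        )
    ]
    return pd.DataFrame(rows)
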