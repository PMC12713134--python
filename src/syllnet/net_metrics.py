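"""Node-level measures on directed weighted behavior networks.

Six measures characterize a per-animal behavior network: strength (weighted
edge count), average neighbor degree, average degree connectivity, closeness
vitality (via the Wiener index), betweenness centrality, and closeness
centrality.

Distances
---------
The path-based measures need a weight -> length convention, selected by
``weight_mode``:

``raw``
    edge length = transition frequency.  This treats the frequency weight
    directly as a length, the convention under which the original analyses
    were run (it is the graph library's default reading of ``weight``), and
    is therefore the package default.
``inverse``
    edge length = 1 / frequency, the frequency-as-affinity reading: heavily
    used transitions are "short".
``unweighted``
    every edge has length 1.

All measures are computed on simple directed graphs; the replicated
multigraph representation (parallel unit edges) is supported for strength,
where it is numerically identical to the weighted form.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import LabelMap

__all__ = [
    "WEIGHT_MODES",
    "DISCONNECT_SENTINEL",
    "strength",
    "total_degree",
    "average_neighbor_degree",
    "average_degree_connectivity",
    "DistanceOracle",
    "all_pairs_distances",
    "wiener_index",
    "closeness_vitality",
    "closeness_vitality_all",
    "betweenness_centrality",
    "closeness_centrality",
    "summarize_distribution",
    "node_metric_table",
    "degree_connectivity_table",
]

WEIGHT_MODES = ("raw", "inverse", "unweighted")

#: Vitality value reported when removing the node disconnects a previously
#: connected pair (the removal makes the remaining Wiener sum blow up).
DISCONNECT_SENTINEL = float("-inf")


def _edge_length(weight: float, mode: str) -> float:
    if mode == "raw":
        length = float(weight)
    elif mode == "inverse":
        length = 1.0 / float(weight)
    elif mode == "unweighted":
        return 1.0
    else:
        raise ValueError(f"unknown weight_mode {mode!r}; expected one of {WEIGHT_MODES}")
    if length <= 0 or not math.isfinite(length):
        raise ValueError(f"nonpositive edge length from weight {weight!r}")
    return length


def _length_graph(net: nx.DiGraph, mode: str) -> nx.DiGraph:
    if net.is_multigraph():
        raise TypeError(
            "path-based measures operate on the weighted simple digraph, "
            "not the replicated multigraph"
        )
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for u, v, d in net.edges(data=True):
        g.add_edge(u, v, length=_edge_length(d.get("weight", 1), mode))
    return g


# ------------------------------------------------------------------ strength

def strength(net: nx.DiGraph | nx.MultiDiGraph, node, direction: str = "total") -> float:
    """Weighted edge count of a node: sum of incident edge weights.

    ``direction`` selects incoming edges, outgoing edges, or both.  On the
    replicated multigraph this equals the number of parallel unit edges.
    """
    if node not in net:
        raise KeyError(f"unknown node {node!r}")
    if direction not in ("in", "out", "total"):
        raise ValueError("direction must be 'in', 'out' or 'total'")
    s = 0.0
    if direction in ("in", "total"):
        s += sum(d.get("weight", 1) for _, _, d in net.in_edges(node, data=True))
    if direction in ("out", "total"):
        s += sum(d.get("weight", 1) for _, _, d in net.out_edges(node, data=True))
    return float(s)


def total_degree(net: nx.DiGraph, node) -> int:
    """Unweighted edge count (in-degree + out-degree)."""
    return int(net.in_degree(node) + net.out_degree(node))


# -------------------------------------------------- neighbor-degree measures

def _pair_weight(net: nx.DiGraph, i, j) -> float:
    """Summed weight of all edges between i and j, both directions."""
    w = 0.0
    if net.has_edge(i, j):
        w += net[i][j].get("weight", 1)
    if net.has_edge(j, i):
        w += net[j][i].get("weight", 1)
    return w


def average_neighbor_degree(net: nx.DiGraph, node) -> float:
    """Strength-weighted mean edge count of a node's neighborhood.

    k_nn,i^w = (1/s_i) * sum over j in N_i of w_ij * k_j, where N_i is the
    union of predecessors and successors of i, w_ij the summed weight of the
    edges linking i and j in either direction, k_j the (unweighted) total
    degree of j, and s_i the total strength of i.  Undefined (NaN) for
    isolated nodes.
    """
    if node not in net:
        raise KeyError(f"unknown node {node!r}")
    s_i = strength(net, node, "total")
    if s_i == 0:
        return float("nan")
    neighbors = set(net.predecessors(node)) | set(net.successors(node))
    acc = 0.0
    for j in neighbors:
        acc += _pair_weight(net, node, j) * total_degree(net, j)
    return acc / s_i


def average_degree_connectivity(net: nx.DiGraph) -> dict[int, float]:
    """Mean average-neighbor-degree of nodes grouped by total degree.

    Keys are the degrees observed among non-isolated nodes; isolated nodes
    (strength 0) are excluded since their neighbor degree is undefined.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    by_degree: dict[int, list[float]] = {}
    for node in net.nodes:
        k = total_degree(net, node)
        if k == 0:
            continue
        by_degree.setdefault(k, []).append(average_neighbor_degree(net, node))
    return {k: float(np.mean(v)) for k, v in sorted(by_degree.items())}


# ----------------------------------------------------------------- distances

@dataclass
class DistanceOracle:
    """All-pairs shortest-path distances and path counts under one mode.

    ``dist[s][t]`` holds d(s, t) for reachable t only (d(s, s) = 0);
    ``sigma[s][t]`` the number of distinct shortest s -> t paths.
    """

    nodes: list
    dist: dict
    sigma: dict

    def reachable(self, s, t) -> bool:
        return t in self.dist.get(s, {})


def _dijkstra_counting(g: nx.DiGraph, source) -> tuple[dict, dict]:
    """Single-source shortest distances and shortest-path counts."""
    dist: dict = {}
    sigma: dict = {source: 1}
    seen = {source: 0.0}
    heap: list = [(0.0, 0, source)]
    tiebreak = 1
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v, edata in g[u].items():
            nd = d + edata["length"]
            if v in dist:
                if math.isclose(nd, dist[v], rel_tol=1e-12, abs_tol=1e-12):
                    sigma[v] = sigma.get(v, 0) + sigma[u]
                continue
            if v not in seen or nd < seen[v] - 1e-15:
                seen[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, tiebreak, v))
                tiebreak += 1
            elif math.isclose(nd, seen[v], rel_tol=1e-12, abs_tol=1e-12):
                sigma[v] = sigma.get(v, 0) + sigma[u]
    return dist, sigma


def all_pairs_distances(net: nx.DiGraph, weight_mode: str = "raw") -> DistanceOracle:
    """Shortest-path distances and counts for every ordered node pair."""
    g = _length_graph(net, weight_mode)
    dist: dict = {}
    sigma: dict = {}
    for s in g.nodes:
        dist[s], sig = _dijkstra_counting(g, s)
        sigma[s] = sig
    return DistanceOracle(nodes=list(g.nodes), dist=dist, sigma=sigma)


def wiener_index(net: nx.DiGraph, weight_mode: str = "raw") -> float:
    """W_G: sum of shortest-path distances over ordered reachable pairs."""
    oracle = all_pairs_distances(net, weight_mode)
    return float(
        sum(
            d
            for s, row in oracle.dist.items()
            for t, d in row.items()
            if s != t
        )
    )


def _wiener_and_pairs(net: nx.DiGraph, weight_mode: str) -> tuple[float, set]:
    oracle = all_pairs_distances(net, weight_mode)
    pairs = {
        (s, t)
        for s, row in oracle.dist.items()
        for t in row
        if s != t
    }
    w = float(sum(oracle.dist[s][t] for s, t in pairs))
    return w, pairs


def closeness_vitality(net: nx.DiGraph, node, weight_mode: str = "raw") -> float:
    """Change in the Wiener index when the node is removed: W(G) - W(G - v).

    When deleting the node disconnects a pair of the remaining nodes that
    was connected before, the removal's cost is unbounded under the
    definition; the sentinel ``-inf`` is returned so distributions keep one
    entry per node.
    """
    if node not in net:
        raise KeyError(f"unknown node {node!r}")
    w_full, pairs_full = _wiener_and_pairs(net, weight_mode)
    reduced = net.copy()
    reduced.remove_node(node)
    w_red, pairs_red = _wiener_and_pairs(reduced, weight_mode)
    surviving = {(s, t) for s, t in pairs_full if s != node and t != node}
    if surviving - pairs_red:
        return DISCONNECT_SENTINEL
    return w_full - w_red


def closeness_vitality_all(net: nx.DiGraph, weight_mode: str = "raw") -> dict:
    return {v: closeness_vitality(net, v, weight_mode) for v in net.nodes}


# ---------------------------------------------------------------- centrality

def betweenness_centrality(
    net: nx.DiGraph, weight_mode: str = "raw", normalized: bool = False
) -> dict:
    """c_B(v) = sum over ordered pairs s != v != t of sigma_st(v) / sigma_st.

    Unreachable pairs contribute 0.  Unnormalized by default; with
    ``normalized=True`` values are divided by (n-1)(n-2).
    """
    g = _length_graph(net, weight_mode)
    weight = None if weight_mode == "unweighted" else "length"
    return nx.betweenness_centrality(g, normalized=normalized, weight=weight)


def closeness_centrality(
    net: nx.DiGraph, node=None, weight_mode: str = "raw"
):
    """Reciprocal mean shortest *incoming* path length, reachability-scaled.

    With r the number of nodes that can reach u,
    ``C(u) = ((r - 1) / sum_v d(v, u)) * ((r - 1) / (n - 1))``; on a strongly
    connected graph this reduces to the plain (n-1)/sum formula.  A node
    nothing can reach scores 0.
    """
    g = _length_graph(net, weight_mode)
    distance = None if weight_mode == "unweighted" else "length"
    if node is not None:
        if node not in net:
            raise KeyError(f"unknown node {node!r}")
        return float(nx.closeness_centrality(g, u=node, distance=distance))
    return {v: float(c) for v, c in nx.closeness_centrality(g, distance=distance).items()}


# ----------------------------------------------------------------- summaries

def summarize_distribution(values: Iterable[float]) -> dict[str, float]:
    """First quartile and robust max of a metric distribution.

    ``first_quartile`` is the 25th percentile with linear interpolation;
    ``robust_max`` is the mean of the three largest values (NaN when fewer
    than three values are supplied).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    q1 = float(np.percentile(arr, 25))
    robust_max = float(np.mean(np.sort(arr)[-3:])) if arr.size >= 3 else float("nan")
    return {"first_quartile": q1, "robust_max": robust_max}


# -------------------------------------------------------------------- tables

def node_metric_table(
    net: nx.DiGraph,
    weight_mode: str = "raw",
    labels: LabelMap | None = None,
    animal_id: str = "",
) -> pd.DataFrame:
    """Per-node table of the five node-level measures for one network."""
    betw = betweenness_centrality(net, weight_mode)
    close = closeness_centrality(net, weight_mode=weight_mode)
    rows = []
    for node in net.nodes:
        rows.append(
            {
                "animal_id": animal_id,
                "node": node,
                "behavior": labels.name(node) if labels else "",
                "strength": strength(net, node, "total"),
                "avg_neighbor_degree": average_neighbor_degree(net, node),
                "closeness_vitality": closeness_vitality(net, node, weight_mode),
                "betweenness": betw[node],
                "closeness": close[node],
            }
        )
    return pd.DataFrame(rows)


def degree_connectivity_table(net: nx.DiGraph, animal_id: str = "") -> pd.DataFrame:
    table = average_degree_connectivity(net)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "degree": list(table.keys()),
            "value": list(table.values()),
        }
    )
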