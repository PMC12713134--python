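"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths (and networkx's
shortest-path machinery): distances come from Floyd-Warshall over an explicit
length matrix, path counts and betweenness from exhaustive simple-path
enumeration.  They are only feasible on small graphs, which is the point.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

INF = math.inf


def edge_length(w: float, mode: str) -> float:
    if mode == "raw":
        return float(w)
    if mode == "inverse":
        return 1.0 / float(w)
    if mode == "unweighted":
        return 1.0
    raise ValueError(mode)


def floyd_warshall(net: nx.DiGraph, mode: str) -> tuple[list, np.ndarray]:
    nodes = list(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for u, v, data in net.edges(data=True):
        w = edge_length(data.get("weight", 1), mode)
        d[idx[u], idx[v]] = min(d[idx[u], idx[v]], w)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return nodes, d


def wiener_fw(net: nx.DiGraph, mode: str) -> float:
    """Wiener index over ordered reachable pairs, via Floyd-Warshall."""
    _, d = floyd_warshall(net, mode)
    off = d[~np.eye(d.shape[0], dtype=bool)]
    return float(off[np.isfinite(off)].sum())


def vitality_fw(net: nx.DiGraph, node, mode: str) -> float:
    """W(G) - W(G - v); -inf when a surviving pair loses connectivity."""
    nodes, d = floyd_warshall(net, mode)
    i = nodes.index(node)
    reduced = net.copy()
    reduced.remove_node(node)
    nodes_r, d_r = floyd_warshall(reduced, mode)
    pos = {v: k for k, v in enumerate(nodes_r)}
    for a in nodes_r:
        for b in nodes_r:
            if a != b and math.isfinite(d[nodes.index(a), nodes.index(b)]) \
                    and not math.isfinite(d_r[pos[a], pos[b]]):
                return -INF
    return wiener_fw(net, mode) - wiener_fw(reduced, mode)


def _all_shortest_path_counts(net: nx.DiGraph, mode: str):
    """sigma[s][t] and sigma_through[v][(s,t)] by simple-path enumeration."""
    nodes = list(net.nodes)
    lengths = {
        (u, v): edge_length(d.get("weight", 1), mode)
        for u, v, d in net.edges(data=True)
    }
    ref, dmat = floyd_warshall(net, mode)
    idx = {v: i for i, v in enumerate(ref)}
    sigma: dict = {}
    through: dict = {v: {} for v in nodes}

    def paths(s, t):
        # All simple s->t paths, DFS.
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                yield path
                continue
            for v in net.successors(u):
                if v not in path:
                    stack.append((v, path + [v]))

    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best = dmat[idx[s], idx[t]]
            if not math.isfinite(best):
                continue
            count = 0
            inner_counts = {v: 0 for v in nodes}
            for p in paths(s, t):
                plen = sum(lengths[(a, b)] for a, b in zip(p[:-1], p[1:]))
                if math.isclose(plen, best, rel_tol=1e-9, abs_tol=1e-12):
                    count += 1
                    for v in p[1:-1]:
                        inner_counts[v] += 1
            sigma[(s, t)] = count
            for v in nodes:
                if inner_counts[v]:
                    through[v][(s, t)] = inner_counts[v]
    return sigma, through


def betweenness_enum(net: nx.DiGraph, mode: str) -> dict:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    sigma, through = _all_shortest_path_counts(net, mode)
    out = {}
    for v in net.nodes:
        total = 0.0
        for (s, t), cnt in through[v].items():
            if s != v and t != v:
                total += cnt / sigma[(s, t)]
        out[v] = total
    return out


def closeness_fw(net: nx.DiGraph, node, mode: str) -> float:
    """Reachability-scaled incoming closeness from Floyd-Warshall distances."""
    nodes, d = floyd_warshall(net, mode)
    n = len(nodes)
    j = nodes.index(node)
    col = d[:, j]
    incoming = [col[i] for i in range(n) if i != j and math.isfinite(col[i])]
    r = len(incoming) + 1
    if r == 1 or sum(incoming) == 0:
        return 0.0
    return ((r - 1) / sum(incoming)) * ((r - 1) / (n - 1))


def random_digraph(rng: np.random.Generator, max_nodes: int = 8,
                   max_weight: int = 9, dyadic: bool = False) -> nx.DiGraph:
    """Random weighted digraph with integer weights >= 1, no self-loops.

    With ``dyadic=True`` weights are powers of two, so inverse lengths (1/w)
    are exact in binary floating point and shortest-path ties are counted
    identically by any correct implementation.
    """
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.7))
    choices = (1, 2, 4, 8) if dyadic else tuple(range(1, max_weight + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in itertools.permutations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v, weight=int(choices[rng.integers(len(choices))]))
    return g
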