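"""Transition matrices and directed weighted behavior networks.

Each ordered pair of consecutive emissions ``S_t -> S_{t+1}`` is one
transition; per-animal counts over all ordered syllable pairs form the
(non-normalized) transition matrix.  The matrix maps directly onto a directed
graph whose nodes are syllables and whose edges carry the transition
frequency as weight.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .datatypes import LabelMap, SyllableSequence, TransitionMatrix

__all__ = [
    "count_transitions",
    "usage_counts",
    "syllable_inclusion",
    "build_network",
    "replicate_edges",
    "node_partition",
]


def count_transitions(
    seq: SyllableSequence | Sequence[int],
    included_ids: Iterable[int] | None = None,
    break_at_gaps: bool = False,
) -> TransitionMatrix:
    """Count ``S_t -> S_{t+1}`` transitions of one sequence.

    When ``included_ids`` is given, emissions outside the set are dropped
    before pairing, so surviving emissions that were separated by excluded
    ones become adjacent.  With ``break_at_gaps=True`` the sequence is
    instead split at excluded emissions and pairs are only counted within
    contiguous surviving stretches.
    """
    s = seq.emissions if isinstance(seq, SyllableSequence) else np.asarray(seq, dtype=np.int64)
    if s.size < 2:
        raise ValueError("transition counting needs at least 2 emissions")
    if included_ids is not None:
        ids = sorted(int(i) for i in included_ids)
        keep = np.isin(s, ids)
        if break_at_gaps:
            pairs_a, pairs_b = [], []
            for chunk in np.split(s, np.flatnonzero(~keep)):
                chunk = chunk[np.isin(chunk, ids)]
                if chunk.size >= 2:
                    pairs_a.append(chunk[:-1])
                    pairs_b.append(chunk[1:])
            a = np.concatenate(pairs_a) if pairs_a else np.empty(0, dtype=np.int64)
            b = np.concatenate(pairs_b) if pairs_b else np.empty(0, dtype=np.int64)
        else:
            surv = s[keep]
            a, b = surv[:-1], surv[1:]
    else:
        ids = sorted(np.unique(s).tolist())
        a, b = s[:-1], s[1:]
    pos = {v: k for k, v in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    if a.size:
        ai = np.array([pos[v] for v in a.tolist()])
        bi = np.array([pos[v] for v in b.tolist()])
        np.add.at(counts, (ai, bi), 1)
    return TransitionMatrix(syllable_ids=ids, counts=counts)


def usage_counts(seqs: Iterable[SyllableSequence]) -> dict[int, int]:
    """Total emission count per syllable across a set of sequences."""
    total: dict[int, int] = {}
    for seq in seqs:
        uniq, cnt = np.unique(seq.emissions, return_counts=True)
        for u, c in zip(uniq.tolist(), cnt.tolist()):
            total[u] = total.get(u, 0) + c
    return total


def syllable_inclusion(
    usage: Mapping[int, float], coverage: float = 0.99
) -> set[int]:
    """Smallest high-usage syllable set reaching the coverage fraction.

    Syllables are ranked by descending usage (ties broken by ascending id)
    and the shortest prefix whose cumulative usage fraction reaches
    ``coverage`` is returned.  This is the usual motion-sequencing convention
    for "syllables explaining 99% of the behavior".
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    if not usage:
        raise ValueError("empty usage counts")
    ranked = sorted(
        ((i, c) for i, c in usage.items() if c > 0),
        key=lambda ic: (-ic[1], ic[0]),
    )
    total = float(sum(c for _, c in ranked))
    if total <= 0:
        raise ValueError("usage counts sum to zero")
    included: set[int] = set()
    cum = 0.0
    for i, c in ranked:
        included.add(int(i))
        cum += c
        if cum / total >= coverage - 1e-12:
            break
    return included


def build_network(
    m: TransitionMatrix,
    labels: LabelMap | None = None,
    keep_isolated: bool = False,
) -> nx.DiGraph:
    """Directed graph with one weighted edge per nonzero matrix cell.

    Nodes are the syllables with at least one incident transition; pass
    ``keep_isolated=True`` to retain the full id universe of the matrix.
    """
    g = nx.DiGraph(replicated=False)
    ids = m.syllable_ids
    if keep_isolated:
        g.add_nodes_from(ids)
    rows, cols = np.nonzero(m.counts)
    for r, c in zip(rows, cols):
        g.add_edge(ids[r], ids[c], weight=int(m.counts[r, c]))
    if labels is not None:
        for node in g.nodes:
            g.nodes[node]["behavior"] = labels.name(node)
    return g


def replicate_edges(net: nx.DiGraph) -> nx.MultiDiGraph:
    """Expand each weight-w edge into w parallel unit-weight edges.

    E.g. one edge 2 -> 4 with weight 20 becomes 20 parallel edges of weight
    1; node strengths are unchanged, only the edge representation differs.
    """
    g = nx.MultiDiGraph(replicated=True)
    g.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        w = int(d.get("weight", 1))
        for _ in range(w):
            g.add_edge(u, v, weight=1)
    return g


def node_partition(
    nets_by_group: Mapping[str, Sequence[nx.DiGraph]],
) -> tuple[set[int], dict[str, set[int]]]:
    """Split nodes into shared vs. group-specific sets.

    A node is specific to a group when it appears in at least one of that
    group's networks and in none of any other group's; every other observed
    node is shared.
    """
    if len(nets_by_group) < 2:
        raise ValueError("node partition needs at least 2 groups")
    seen: dict[str, set[int]] = {}
    for group, nets in nets_by_group.items():
        nets = list(nets)
        if not nets:
            raise ValueError(f"group {group!r} has no networks")
        seen[group] = set().union(*(set(n.nodes) for n in nets))
    specific: dict[str, set[int]] = {}
    for group, nodes in seen.items():
        others = set().union(*(v for g, v in seen.items() if g != group))
        specific[group] = nodes - others
    all_nodes = set().union(*seen.values())
    shared = all_nodes - set().union(*specific.values())
    return shared, specific
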