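"""Agglomerative fast-greedy modularity communities, with a brute-force oracle.

Newman modularity of a partition: Q = sum_c (e_cc - a_c^2), where e_cc is
the fraction of (weighted) edge mass inside community c and a_c the fraction
of (weighted) degree attached to c.  The fast-greedy algorithm starts from
singleton communities and repeatedly merges the *connected* pair of
communities with the largest modularity gain (ties broken by the
lexicographically smallest community-id pair, so runs are deterministic),
recording the full dendrogram; the returned partition is the cut with
maximal modularity.  An exhaustive set-partition search over graphs of at
most ``max_nodes`` nodes serves as an independent optimum oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


def _edge_weight(data: dict, weighted: bool, weight_attr: str) -> float:
    return float(data.get(weight_attr, 1.0)) if weighted else 1.0


def modularity(
    G: nx.Graph,
    partition: dict,
    weighted: bool = True,
    weight_attr: str = "mi",
) -> float:
    """Newman modularity Q of a node->community mapping."""
    if set(partition) != set(G.nodes):
        raise ValueError("partition must cover every node exactly once")
    m = 0.0
    inner: dict = {}
    deg: dict = {}
    for u, v, d in G.edges(data=True):
        w = _edge_weight(d, weighted, weight_attr)
        m += w
        deg[partition[u]] = deg.get(partition[u], 0.0) + w
        deg[partition[v]] = deg.get(partition[v], 0.0) + w
        if partition[u] == partition[v]:
            inner[partition[u]] = inner.get(partition[u], 0.0) + w
    if m <= 0:
        raise ValueError("modularity is undefined for an edgeless network")
    q = 0.0
    communities = set(partition.values())
    for c in communities:
        e_cc = inner.get(c, 0.0) / m
        a_c = deg.get(c, 0.0) / (2.0 * m)
        q += e_cc - a_c * a_c
    return float(q)


@dataclass
class Dendrogram:
    """Merge sequence of the agglomerative search.

    ``merges`` holds (community_a, community_b, delta_q, q_after) in merge
    order; ``q_start`` is the singleton-partition modularity; ``best_cut``
    is the number of merges applied at the modularity maximum (0 =
    singletons); ``partition`` maps node -> community id at the best cut.
    """

    merges: list[tuple]
    q_start: float
    best_cut: int
    partition: dict
    q_best: float

    @property
    def q_trace(self) -> list[float]:
        qs = [self.q_start]
        for *_, q_after in self.merges:
            qs.append(q_after)
        return qs

    def n_communities(self, n_nodes: int) -> int:
        return n_nodes - self.best_cut


def fast_greedy(
    G: nx.Graph,
    weighted: bool = True,
    weight_attr: str = "mi",
) -> Dendrogram:
    """Greedy bottom-up modularity maximization (CNM-style).

    Deterministic: the community id is the smallest member node (by sorted
    order), and ties in the modularity gain are broken by the smallest id
    pair.  Merging continues across each connected component until no
    connected community pair remains, so the dendrogram is complete even
    when every remaining gain is negative; the reported partition is the cut
    with maximal Q.
    """
    nodes = sorted(G.nodes)
    if len(nodes) < 2:
        return Dendrogram(
            merges=[],
            q_start=0.0,
            best_cut=0,
            partition={n: n for n in nodes},
            q_best=0.0,
        )
    m = sum(_edge_weight(d, weighted, weight_attr) for _, _, d in G.edges(data=True))
    if m <= 0:
        raise ValueError("fast_greedy requires at least one (positively weighted) edge")

    # community state keyed by the smallest member node
    members: dict = {n: {n} for n in nodes}
    deg: dict = {n: 0.0 for n in nodes}
    between: dict = {n: {} for n in nodes}  # inter-community weights
    inner: dict = {n: 0.0 for n in nodes}
    for u, v, d in G.edges(data=True):
        w = _edge_weight(d, weighted, weight_attr)
        deg[u] += w
        deg[v] += w
        if u == v:
            inner[u] += w
        else:
            between[u][v] = between[u].get(v, 0.0) + w
            between[v][u] = between[v].get(u, 0.0) + w

    q = sum(inner[c] / m - (deg[c] / (2 * m)) ** 2 for c in members)
    q_start = q
    merges: list[tuple] = []

    def current_partition() -> dict:
        return {n: cid for cid, mem in members.items() for n in mem}

    snapshots = [current_partition()]

    while True:
        best = None
        for a in sorted(between):
            for b in sorted(between[a]):
                if b <= a:
                    continue
                dq = between[a][b] / m - 2.0 * (deg[a] / (2 * m)) * (deg[b] / (2 * m))
                if best is None or dq > best[0] + 1e-12:
                    best = (dq, a, b)
        if best is None:
            break
        dq, a, b = best
        # merge b into a (a < b)
        inner[a] += inner.pop(b) + between[a].pop(b)
        del between[b][a]
        for c, w in between.pop(b).items():
            between[c].pop(b)
            between[a][c] = between[a].get(c, 0.0) + w
            between[c][a] = between[a][c]
        deg[a] += deg.pop(b)
        members[a] |= members.pop(b)
        q += dq
        merges.append((a, b, float(dq), float(q)))
        snapshots.append(current_partition())

    q_trace = [q_start] + [mq for *_, mq in merges]
    best_cut = int(np.argmax(q_trace))
    return Dendrogram(
        merges=merges,
        q_start=float(q_start),
        best_cut=best_cut,
        partition=snapshots[best_cut],
        q_best=float(q_trace[best_cut]),
    )


def _set_partitions(items: list):
    """Yield all set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_force_best_partition(
    G: nx.Graph,
    max_nodes: int = 10,
    weighted: bool = True,
    weight_attr: str = "mi",
) -> tuple[dict, float]:
    """Global modularity optimum by exhaustive set-partition search.

    Refuses graphs larger than ``max_nodes`` (Bell numbers explode) and
    edgeless graphs (Q undefined).  Returns (node->community mapping with
    the smallest member as id, Q*).
    """
    nodes = sorted(G.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {len(nodes)}")
    if G.number_of_edges() == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    best_q = -np.inf
    best: dict = {}
    for blocks in _set_partitions(nodes):
        part = {n: min(block) for block in blocks for n in block}
        q = modularity(G, part, weighted=weighted, weight_attr=weight_attr)
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best, float(best_q)


def partition_to_labels(partition: dict, nodes=None) -> np.ndarray:
    """Integer label vector of a partition (for e.g. adjusted Rand index)."""
    nodes = sorted(partition) if nodes is None else list(nodes)
    ids = {cid: k for k, cid in enumerate(dict.fromkeys(partition[n] for n in nodes))}
    return np.array([ids[partition[n]] for n in nodes])
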