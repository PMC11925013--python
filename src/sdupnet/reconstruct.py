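"""Reconstruction of primary duplication events as a minimum spanning forest.

Every node of an SD-network component except the founding pair arose by
duplication of one of its neighbors, and a daughter shares more neighbors
with its mother than with anyone else.  Edges are therefore weighted by

    w(a, b) = 1 - |N(a) & N(b)| / min(k_a, k_b)

(shared-neighbor overlap; ``N`` excludes the node itself, ``k`` is degree),
so that likely primary edges are light, and the per-component minimum
spanning tree — Kruskal over the weighted simple graph — is taken as the
predicted set of primary duplication events.  Edges flagged as suspicious
(matching breakpoints, see :mod:`sdupnet.core`) get a penalty weight above 1
so they are only ever used when a component offers no alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "edge_weight",
    "assign_weights",
    "minimum_spanning_forest",
    "SpanningForest",
    "duplication_counts",
    "mst_enrichment_test",
]

SUSPICIOUS_PENALTY = 2.0


def edge_weight(net: nx.Graph, a, b) -> float:
    """Shared-neighbor weight of an existing edge; in (0, 1].

    Equals 1 exactly when the endpoints share no neighbors; it is always
    positive because ``a`` is never in ``N(a)`` and ``b`` never in ``N(b)``,
    so the overlap is strictly smaller than either neighborhood.
    """
    if a == b:
        raise ValueError("self-loop: edge weight is undefined for a == b")
    if not net.has_edge(a, b):
        raise ValueError(f"edge ({a}, {b}) is not in the network")
    na = set(net.neighbors(a))
    nb = set(net.neighbors(b))
    shared = len(na & nb)
    return 1.0 - shared / min(len(na), len(nb))


def assign_weights(net: nx.Graph, suspicious_penalty: float = SUSPICIOUS_PENALTY) -> nx.Graph:
    """Set the ``weight`` attribute on every edge (in place; net returned).

    Suspicious edges get ``suspicious_penalty`` (> 1), which guarantees they
    lose to any non-suspicious alternative during forest construction.
    """
    any_penalized_component = False
    for u, v, data in net.edges(data=True):
        if data.get("suspicious", False):
            data["weight"] = suspicious_penalty
        else:
            data["weight"] = edge_weight(net, u, v)
    # warn when a component consists of suspicious edges only: the forest
    # will have to use penalty edges there
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if sub.number_of_edges() and all(d.get("suspicious", False) for _, _, d in sub.edges(data=True)):
            warnings.warn(
                "a connected component contains only suspicious edges; "
                "penalty edges will appear in the spanning forest",
                stacklevel=2,
            )
            any_penalized_component = True
    net.graph["penalized_component"] = any_penalized_component
    return net


@dataclass
class SpanningForest:
    """Predicted primary-event forest: edge subset plus per-node counts."""

    edges: set
    duplication_count: dict = field(default_factory=dict)
    total_weight: float = 0.0

    def __contains__(self, edge) -> bool:
        u, v = edge
        return (u, v) in self.edges or (v, u) in self.edges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.rank = {x: 0 for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def minimum_spanning_forest(net: nx.Graph, seed: int = 0, weight: str = "weight") -> SpanningForest:
    """Kruskal's minimum spanning forest with seeded, stable tie-breaking.

    Edges of equal weight are ordered by a seeded random key so repeated
    runs with the same seed are bit-identical while different seeds explore
    different optimal forests when ties exist.  The forest has exactly
    ``n_nodes - n_components`` edges.
    """
    rng = np.random.default_rng(seed)
    edges = list(net.edges(data=True))
    tie_keys = rng.permutation(len(edges))
    order = sorted(range(len(edges)), key=lambda i: (edges[i][2][weight], tie_keys[i]))
    uf = _UnionFind(net.nodes)
    chosen: set = set()
    total = 0.0
    for i in order:
        u, v, data = edges[i]
        if uf.union(u, v):
            chosen.add((u, v))
            total += data[weight]
    forest = SpanningForest(edges=chosen, total_weight=total)
    forest.duplication_count = duplication_counts(forest, net.nodes)
    n_comp = nx.number_connected_components(net)
    assert len(chosen) == net.number_of_nodes() - n_comp
    return forest


def duplication_counts(forest: SpanningForest, nodes) -> dict:
    """Per-node duplication count = degree within the forest.

    The number of events a node took part in is its forest degree; this is
    invariant to the (unknown) choice of founding node in each component,
    which would only shift counts at the roots.
    """
    counts = {n: 0 for n in nodes}
    for u, v in forest.edges:
        counts[u] += 1
        counts[v] += 1
    return counts


def mst_enrichment_test(
    net: nx.Graph,
    forest: SpanningForest,
    edge_predicate,
    direction: str = "greater",
    n_rounds: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation test: is the forest enriched/depleted in predicate edges?

    The observed statistic is the number of forest edges satisfying
    ``edge_predicate(u, v, data)``.  Each background round draws
    ``|forest|`` edges uniformly without replacement from the non-forest
    edges and recomputes the count.  The empirical p-value uses the add-one
    convention ``p = (1 + #{as extreme}) / (n_rounds + 1)`` so it is never
    exactly zero.

    direction: "greater" tests enrichment (background >= observed counts as
    extreme), "less" tests depletion.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    forest_edges = [e for e in net.edges if e in forest]
    rest = [e for e in net.edges if e not in forest]
    k = len(forest_edges)
    if len(rest) < k:
        raise ValueError(
            f"cannot draw {k} edges from only {len(rest)} non-forest edges"
        )
    flags_rest = np.array([bool(edge_predicate(u, v, net.edges[u, v])) for u, v in rest])
    observed = sum(bool(edge_predicate(u, v, net.edges[u, v])) for u, v in forest_edges)

    rng = np.random.default_rng(seed)
    hits = 0
    n_rest = len(rest)
    for _ in range(n_rounds):
        draw = rng.choice(n_rest, size=k, replace=False)
        stat = int(flags_rest[draw].sum())
        if direction == "greater":
            extreme = stat >= observed
        else:
            extreme = stat <= observed
        hits += extreme
    p = (1 + hits) / (n_rounds + 1)
    return {
        "observed": int(observed),
        "n_rounds": n_rounds,
        "direction": direction,
        "p_value": p,
    }
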