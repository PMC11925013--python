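"""Accuracy scoring of event reconstruction against simulation truth.

Two complementary metrics: the fraction of predicted-forest edges that are
true primary duplications, and the variance in per-node duplication counts
explained by a predicted node score.  The latter is the squared Pearson
correlation, which puts count predictors (forest degree, raw degree) and
arbitrary-scale centralities on the same footing.
"""

from __future__ import annotations

from dataclasses import replace

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .pcm import SimParams, SimulatedNetwork, simulate
from .reconstruct import SpanningForest, assign_weights, minimum_spanning_forest

__all__ = [
    "edges_match",
    "variance_explained",
    "centrality_baselines",
    "random_spanning_forest",
    "benchmark",
    "CENTRALITY_METHODS",
]

CENTRALITY_METHODS = ("betweenness", "closeness", "eigenvector", "pagerank", "radiality")


def _as_edge_set(edges) -> set:
    if isinstance(edges, SpanningForest):
        edges = edges.edges
    return {(u, v) if u <= v else (v, u) for u, v in edges}


def edges_match(predicted, truth: SimulatedNetwork | set) -> float:
    """Percent of predicted edges that are true primary duplications."""
    pred = _as_edge_set(predicted)
    if not pred:
        raise ValueError("predicted edge set is empty")
    primary = _as_edge_set(truth if isinstance(truth, set) else truth.primary_edges())
    return 100.0 * len(pred & primary) / len(pred)


def variance_explained(pred, truth) -> float:
    """Squared Pearson correlation between a score vector and true counts."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(truth) == 0:
        raise ValueError("truth vector is constant; variance explained undefined")
    if np.ptp(pred) == 0:
        return 0.0
    r = np.corrcoef(pred, truth)[0, 1]
    return float(r * r)


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in net.edges], directed=False
    )
    return g, nodes


def centrality_baselines(net: nx.Graph, methods=CENTRALITY_METHODS) -> dict:
    """Standard node-centrality vectors used as baselines.

    Betweenness, closeness, eigenvector and radiality are computed per
    connected component and concatenated (a disconnected graph otherwise
    drowns the small components); PageRank (damping 0.85) is computed on
    the whole graph and sums to 1.  Returns ``{method: {node: value}}``.
    """
    g, nodes = _to_igraph(net)
    out: dict[str, dict] = {m: {} for m in methods}
    if "pagerank" in methods:
        pr = g.pagerank(damping=0.85)
        out["pagerank"] = {nodes[i]: pr[i] for i in range(len(nodes))}
    per_comp = [m for m in methods if m != "pagerank"]
    if per_comp:
        membership = g.connected_components().membership
        comps: dict[int, list[int]] = {}
        for i, c in enumerate(membership):
            comps.setdefault(c, []).append(i)
        for comp_nodes in comps.values():
            sub = g.induced_subgraph(comp_nodes)
            n = sub.vcount()
            vals: dict[str, list[float]] = {}
            if "betweenness" in per_comp:
                vals["betweenness"] = sub.betweenness()
            if "closeness" in per_comp:
                vals["closeness"] = [0.0] * n if n == 1 else sub.closeness()
            if "eigenvector" in per_comp:
                vals["eigenvector"] = [1.0] * n if n == 1 else sub.eigenvector_centrality(scale=True)
            if "radiality" in per_comp:
                if n == 1:
                    vals["radiality"] = [0.0]
                else:
                    dist = np.array(sub.distances())
                    diam = dist.max()
                    rad = (diam + 1 - dist).sum(axis=1) - (diam + 1)  # drop self term
                    vals["radiality"] = (rad / (n - 1)).tolist()
            for m, vv in vals.items():
                for local_i, v in enumerate(vv):
                    out[m][nodes[comp_nodes[local_i]]] = float(v)
    return out


def random_spanning_forest(net: nx.Graph, seed: int = 0) -> SpanningForest:
    """Spanning forest from Kruskal on i.i.d. uniform random edge weights."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    tmp = nx.Graph()
    tmp.add_nodes_from(net.nodes)
    for u, v in net.edges:
        tmp.add_edge(u, v, weight=float(rng.random()))
    return minimum_spanning_forest(tmp, seed=seed)


def _strip_truth(sim: SimulatedNetwork) -> nx.Graph:
    """Surviving graph with truth labels removed (what a method may see)."""
    g = nx.Graph()
    g.add_nodes_from(sim.graph.nodes)
    g.add_edges_from(sim.graph.edges)
    return g


def score_methods(
    sim: SimulatedNetwork,
    seed: int = 0,
    methods=("mst", "degrees", "random_tree") + CENTRALITY_METHODS,
) -> dict:
    """Score every requested prediction method on one simulated network.

    Returns ``{method: {"edges_match": % or None, "r2": float}}``.
    """
    g = _strip_truth(sim)
    nodes = list(g.nodes)
    truth = np.array([sim.graph.nodes[n]["true_dup_count"] for n in nodes], dtype=float)
    results: dict[str, dict] = {}

    if "mst" in methods:
        assign_weights(g)
        forest = minimum_spanning_forest(g, seed=seed)
        pred = np.array([forest.duplication_count[n] for n in nodes], dtype=float)
        results["mst"] = {
            "edges_match": edges_match(forest, sim),
            "r2": variance_explained(pred, truth),
        }
    if "degrees" in methods:
        deg = np.array([g.degree(n) for n in nodes], dtype=float)
        results["degrees"] = {"edges_match": None, "r2": variance_explained(deg, truth)}
    if "random_tree" in methods:
        forest = random_spanning_forest(g, seed=seed + 1)
        pred = np.array([forest.duplication_count[n] for n in nodes], dtype=float)
        results["random_tree"] = {
            "edges_match": edges_match(forest, sim),
            "r2": variance_explained(pred, truth),
        }
    wanted = [m for m in CENTRALITY_METHODS if m in methods]
    if wanted:
        cents = centrality_baselines(g, methods=wanted)
        for m in wanted:
            vec = np.array([cents[m][n] for n in nodes], dtype=float)
            results[m] = {"edges_match": None, "r2": variance_explained(vec, truth)}
    return results


def benchmark(
    params: SimParams,
    n_reps: int = 20,
    seed: int = 0,
    methods=("mst", "degrees", "random_tree") + CENTRALITY_METHODS,
) -> pd.DataFrame:
    """Replicate simulations and tabulate mean +/- SE accuracy per method."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        sim = simulate(replace(params, seed=seed + 1009 * rep))
        scores = score_methods(sim, seed=seed + 1009 * rep, methods=methods)
        for method, sc in scores.items():
            rows.append({"rep": rep, "method": method, **sc})
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("method")
        .agg(
            edges_match_mean=("edges_match", "mean"),
            edges_match_se=("edges_match", lambda s: s.std(ddof=1) / np.sqrt(s.notna().sum()) if s.notna().sum() > 1 else 0.0),
            r2_mean=("r2", "mean"),
            r2_se=("r2", lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0),
        )
        .reindex([m for m in methods])
    )
    agg.attrs["per_rep"] = df
    return agg
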