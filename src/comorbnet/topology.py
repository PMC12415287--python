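"""Topological summary panel and paired comparison of two networks.

All metrics are computed on the unweighted graph. Distance-based metrics
(mean shortest-path distance, diameter) are computed on the largest
connected component, flagged when the graph is disconnected. "Degeneracy"
is summarized both as the mean core number over nodes and as the graph
degeneracy (the maximum core number).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import AnalysisError, EpidemiologicalNetwork, SimilarityNetwork

__all__ = ["TopologySummary", "summarize", "assortativity_categorical", "paired_compare"]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_components: int
    mean_degree: float
    density: float
    mean_distance: float
    diameter: float
    mean_transitivity: float
    mean_closeness: float
    mean_betweenness: float
    mean_core_number: float
    degeneracy: float
    assortativity_by_category: float
    disconnected: bool
    empty: bool = False


def _as_graph(net, sign: str | None) -> nx.Graph:
    if isinstance(net, SimilarityNetwork):
        return net.graph(sign)
    if isinstance(net, EpidemiologicalNetwork):
        return net.graph()
    if isinstance(net, nx.Graph):
        return net
    raise TypeError(f"cannot summarize {type(net)!r}")


def summarize(
    net,
    sign: str | None = None,
    categories: dict[str, str] | None = None,
) -> TopologySummary:
    """The full metric panel for one (sign-filtered) network."""
    g = _as_graph(net, sign)
    n = g.number_of_nodes()
    if n == 0:
        raise AnalysisError("empty graph")
    m = g.number_of_edges()
    if m == 0:
        return TopologySummary(
            n_nodes=n, n_edges=0, n_components=n, mean_degree=0.0, density=0.0,
            mean_distance=np.nan, diameter=np.nan, mean_transitivity=np.nan,
            mean_closeness=0.0, mean_betweenness=0.0, mean_core_number=0.0,
            degeneracy=0.0, assortativity_by_category=np.nan,
            disconnected=n > 1, empty=True,
        )
    comps = list(nx.connected_components(g))
    disconnected = len(comps) > 1
    giant = g.subgraph(max(comps, key=len))
    core = nx.core_number(g)
    if categories is not None and len(set(categories.values())) > 1:
        assort = assortativity_categorical(g, categories)
    else:
        assort = np.nan
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        n_components=len(comps),
        mean_degree=2.0 * m / n,
        density=nx.density(g),
        mean_distance=nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else np.nan,
        diameter=float(nx.diameter(giant)) if giant.number_of_nodes() > 1 else np.nan,
        mean_transitivity=nx.transitivity(g),
        mean_closeness=float(np.mean(list(nx.closeness_centrality(g).values()))),
        mean_betweenness=float(np.mean(list(nx.betweenness_centrality(g).values()))),
        mean_core_number=float(np.mean(list(core.values()))),
        degeneracy=float(max(core.values())),
        assortativity_by_category=assort,
        disconnected=disconnected,
    )


def assortativity_categorical(net, labels: dict[str, str], sign: str | None = None) -> float:
    """Newman nominal assortativity from the category mixing matrix.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) over edge-end
    category frequencies; undefined (error) with a single category.
    """
    g = _as_graph(net, sign)
    missing = [v for v in g.nodes if v not in labels]
    if missing:
        raise AnalysisError(f"nodes without category label: {missing[:5]}")
    if len({labels[v] for v in g.nodes}) < 2:
        raise AnalysisError("assortativity undefined with a single category")
    for v in g.nodes:
        g.nodes[v]["_cat"] = labels[v]
    return float(nx.attribute_assortativity_coefficient(g, "_cat"))


NODE_METRICS = ("degree", "closeness", "betweenness", "core_number")


def _node_metric(g: nx.Graph, metric: str) -> dict[str, float]:
    if metric == "degree":
        return dict(g.degree())
    if metric == "closeness":
        return nx.closeness_centrality(g)
    if metric == "betweenness":
        return nx.betweenness_centrality(g)
    if metric == "core_number":
        return nx.core_number(g)
    raise ValueError(f"unknown node metric {metric!r}")


def paired_compare(
    a,
    b,
    metrics: tuple[str, ...] = NODE_METRICS,
    sign: str | None = None,
) -> dict[str, dict]:
    """Paired two-sided t-tests of per-node metrics over common nodes.

    Returns per metric the mean difference (a - b), t, p and a
    ``degenerate`` flag when every paired difference is zero.
    """
    ga, gb = _as_graph(a, sign), _as_graph(b, sign)
    common = sorted(set(ga.nodes) & set(gb.nodes))
    if len(common) < 3:
        raise AnalysisError("need >= 3 common nodes for a paired comparison")
    out = {}
    for metric in metrics:
        va = _node_metric(ga, metric)
        vb = _node_metric(gb, metric)
        xa = np.array([va[v] for v in common], dtype=float)
        xb = np.array([vb[v] for v in common], dtype=float)
        diff = xa - xb
        if np.allclose(diff.std(ddof=1), 0.0):
            out[metric] = dict(
                mean_diff=float(diff.mean()), t=np.nan, pvalue=np.nan,
                degenerate=True, n=len(common),
            )
            continue
        t, p = stats.ttest_rel(xa, xb)
        out[metric] = dict(
            mean_diff=float(diff.mean()), t=float(t), pvalue=float(p),
            degenerate=False, n=len(common),
        )
    return out
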