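"""Correlation and differential-correlation networks over features.

Two network types: (1) a plain correlation network over all samples,
keeping feature pairs whose correlation is significant after BH
correction; (2) a differential-correlation network comparing two groups
with the Fisher z test, Z = (atanh r_a − atanh r_b) / sqrt(1/(n_a−3) +
1/(n_b−3)), keeping pairs whose correlation difference survives BH at
q <= 0.01 — the construction behind disease-vs-control rewiring maps.

Downstream graph work (degree/closeness/betweenness centralities,
fast-greedy modularity communities, GML/Pajek export) delegates to
networkx, with the modularity of the returned partition recomputed from
the direct formula Q = sum_c (e_c/m − (d_c/2m)²).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats as sps

from .core_io import PeakTable, SampleMeta
from .stats import bh_adjust

__all__ = [
    "correlation_network",
    "differential_correlation",
    "graph_centralities",
    "detect_communities",
    "export_graph",
    "modularity",
    "CorrelationGraph",
]

_MIN_OVERLAP = 5  # minimum co-observed samples for a pair to be tested


@dataclasses.dataclass
class CorrelationGraph:
    """Feature graph with correlation edges and optional annotations."""

    graph: nx.Graph
    kind: str                      # "correlation" or "differential"
    communities: dict | None = None
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _pair_correlations(V: np.ndarray, method: str):
    """Correlation and co-observed count for each feature pair (upper triangle)."""
    F = V.shape[0]
    pairs = []
    for i in range(F):
        for j in range(i + 1, F):
            both = np.isfinite(V[i]) & np.isfinite(V[j])
            n = int(both.sum())
            if n < _MIN_OVERLAP:
                continue
            x, y = V[i, both], V[j, both]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # constant feature: correlation undefined
            if method == "pearson":
                r = float(sps.pearsonr(x, y).statistic)
            else:
                r = float(sps.spearmanr(x, y).statistic)
            pairs.append((i, j, r, n))
    return pairs


def correlation_network(
    pt: PeakTable,
    method: str = "pearson",
    q_max: float = 0.05,
) -> CorrelationGraph:
    """All-sample correlation network; edges kept at BH q <= ``q_max``.

    Correlation p-values come from the t transform
    t = r sqrt((n−2)/(1−r²)) with n−2 degrees of freedom.  Pairs with
    fewer than 5 co-observed samples, or involving a constant feature,
    are skipped.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if pt.n_samples < 4:
        raise ValueError("correlation network needs at least 4 samples")
    pairs = _pair_correlations(pt.values, method)
    g = nx.Graph()
    g.add_nodes_from(str(f) for f in pt.feature_ids)
    if not pairs:
        return CorrelationGraph(g, kind="correlation")
    pvals = []
    for (_, _, r, n) in pairs:
        r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
        t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
        pvals.append(2 * sps.t.sf(abs(t), n - 2))
    q = bh_adjust(pvals)
    for (i, j, r, n), pv, qv in zip(pairs, pvals, q):
        if qv <= q_max:
            g.add_edge(
                str(pt.feature_ids[i]), str(pt.feature_ids[j]),
                r=float(r), p=float(pv), q=float(qv), n=n,
            )
    return CorrelationGraph(g, kind="correlation")


def differential_correlation(
    pt: PeakTable,
    meta: SampleMeta,
    group_a: str,
    group_b: str,
    q_max: float = 0.01,
    method: str = "pearson",
) -> CorrelationGraph:
    """Differential-correlation network between two groups (Fisher z test).

    For each feature pair the group correlations r_a, r_b are compared by
    Z = (atanh r_a − atanh r_b)/sqrt(1/(n_a−3) + 1/(n_b−3)) with a
    two-sided normal p-value; edges survive at BH q <= ``q_max``.
    Correlations at |r| = 1 are clipped before atanh with a warning.
    """
    klass = meta.classes(pt.sample_ids)
    cols_a = np.array([k == group_a for k in klass], dtype=bool)
    cols_b = np.array([k == group_b for k in klass], dtype=bool)
    if cols_a.sum() < 5 or cols_b.sum() < 5:
        raise ValueError("each group needs at least 5 samples for differential correlation")
    pa = {(i, j): (r, n) for i, j, r, n in _pair_correlations(pt.values[:, cols_a], method)}
    pb = {(i, j): (r, n) for i, j, r, n in _pair_correlations(pt.values[:, cols_b], method)}
    common = sorted(set(pa) & set(pb))
    g = nx.Graph()
    g.add_nodes_from(str(f) for f in pt.feature_ids)
    if not common:
        return CorrelationGraph(g, kind="differential")
    clip = 1.0 - 1e-12
    clipped = False
    stats = []
    for key in common:
        (ra, na), (rb, nb) = pa[key], pb[key]
        if abs(ra) >= clip or abs(rb) >= clip:
            clipped = True
        za = np.arctanh(np.clip(ra, -clip, clip))
        zb = np.arctanh(np.clip(rb, -clip, clip))
        if na <= 3 or nb <= 3:
            continue
        z = (za - zb) / np.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))
        stats.append((key, ra, rb, float(z), 2 * sps.norm.sf(abs(z))))
    if clipped:
        warnings.warn("correlations at |r| = 1 clipped before Fisher z transform")
    q = bh_adjust([s[-1] for s in stats])
    for (key, ra, rb, z, pv), qv in zip(stats, q):
        if qv <= q_max:
            i, j = key
            g.add_edge(
                str(pt.feature_ids[i]), str(pt.feature_ids[j]),
                r1=float(ra), r2=float(rb), z_diff=z, p=float(pv), q=float(qv),
            )
    return CorrelationGraph(g, kind="differential")


def graph_centralities(cg: CorrelationGraph) -> CorrelationGraph:
    """Attach degree, closeness and betweenness to every node.

    Closeness is (reachable−1)/(sum of distances) within the node's
    component (0 for isolated nodes); betweenness uses unnormalized
    shortest-path pair counts.
    """
    g = cg.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    for node in g.nodes:
        g.nodes[node]["degree"] = int(g.degree[node])
        g.nodes[node]["closeness"] = float(closeness[node])
        g.nodes[node]["betweenness"] = float(betweenness[node])
    return cg


def modularity(g: nx.Graph, partition: list[set]) -> float:
    """Direct-formula modularity Q = sum_c (e_c/m − (d_c/2m)²)."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for community in partition:
        community = set(community)
        e_c = sum(1 for u, v in g.edges if u in community and v in community)
        d_c = sum(g.degree[u] for u in community)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def detect_communities(cg: CorrelationGraph) -> CorrelationGraph:
    """Fast-greedy (Clauset-Newman-Moore) modularity communities.

    Node attributes gain a ``community`` id; the partition's modularity is
    recomputed from the direct formula and stored on the result.  A graph
    with no edges puts every node in its own community with Q = 0.
    """
    g = cg.graph
    if g.number_of_edges() == 0:
        partition = [{n} for n in sorted(g.nodes)]
    else:
        partition = [set(c) for c in nx.community.greedy_modularity_communities(g)]
        # deterministic labelling: communities ordered by smallest member
        partition.sort(key=lambda c: sorted(c)[0])
    communities: dict[str, int] = {}
    for cid, members in enumerate(partition):
        for node in members:
            communities[node] = cid
            g.nodes[node]["community"] = cid
    cg.communities = communities
    cg.modularity = modularity(g, partition)
    return cg


def export_graph(cg: CorrelationGraph, format: str, path: str | Path) -> None:
    """Write the graph as GML (with node/edge attributes) or Pajek NET."""
    path = Path(path)
    if format == "gml":
        nx.write_gml(cg.graph, path)
    elif format == "pajek":
        nx.write_pajek(cg.graph, path)
    else:
        raise ValueError(f"unknown export format {format!r}; use 'gml' or 'pajek'")
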