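"""System, node and edge measures for a configured dynamical network.

System-level scalars qualify the whole network with one value each
(controllability/observability verdicts, density, diameter, degree-based
centralization and variance, degree--degree Pearson correlations along
edges, percentages of self-loops and of symmetric edge pairs, and the
relative degree of the configured system).  Node and edge tables carry the
per-element centralities and control-specific measures (control/observe
centrality, driver classification, controlling/observing distance matrices,
reachability matrices, and similarity measures between drivers or sensors).

Conventions (fixed here so results are reproducible):

* density = E / N^2, counting self-loops;
* betweenness (node and edge) uses directed fractional shortest-path
  counting, endpoints excluded for nodes, unnormalized;
* PageRank: damping 0.85, uniform teleport, dangling mass redistributed
  uniformly, L1 tolerance 1e-12, reported as probabilities summing to 1;
* node relative degree is the raw hop distance from the nearest driver
  (drivers sit at 0), and the system relative degree is the maximum over
  nodes and over the input and output sides;
* degree variance is the population variance of total degree;
* Freeman centralization of total degree, normalized by (N-1)(N-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import (
    DirectedNetwork,
    UNREACHABLE,
    _sort_key,
    distances,
    maximum_matching,
)
from .mapping import InputConfiguration, OutputConfiguration, build_model
from .graph_core import (
    structural_controllability_test,
    structural_observability_test,
)

Node = Hashable

INF = math.inf


@dataclass
class SystemMeasures:
    """Table of system-level scalars."""

    controllability: int
    observability: int
    n_nodes: int
    n_edges: int
    density: float
    diameter: float
    freeman_centrality: float
    degree_variance: float
    relative_degree: float
    pearson_in_in: float
    pearson_in_out: float
    pearson_out_out: float
    pearson_out_in: float
    percent_loops: float
    percent_sym: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def edge_pair_counts(net: DirectedNetwork) -> tuple[int, int, int]:
    """(connected unordered pairs, symmetric pairs, self-loops).

    Every edge is accounted for exactly once in
    ``E = connected_pairs + symmetric_pairs + self_loops``: each connected
    pair contributes one edge, each symmetric pair one extra.
    """
    loops = sum(1 for u, v in net.edges if u == v)
    pairs = {frozenset((u, v)) for u, v in net.edges if u != v}
    symmetric = sum(1 for u, v in net.edges if u != v and (v, u) in net.edges) // 2
    return len(pairs), symmetric, loops


def _pearson(xs, ys) -> float:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def _finite_max(values) -> float:
    finite = [v for v in values if v is not UNREACHABLE]
    return float(max(finite)) if finite else 0.0


def relative_degree(net: DirectedNetwork,
                    input_cfg: InputConfiguration | None = None,
                    output_cfg: OutputConfiguration | None = None) -> float:
    """System relative degree: worst-case hop count between a state and the
    nearest actuator (forward from drivers) or sensor (backward to sensors);
    the maximum of whichever sides are configured.  Unreachable states give
    ``inf``."""
    if input_cfg is None and output_cfg is None:
        raise ValueError("relative degree needs an input or output configuration")
    sides = []
    if input_cfg is not None:
        d = distances(net, input_cfg.actuated_nodes, "forward")
        sides.append(max((INF if v is UNREACHABLE else v) for v in d.values()))
    if output_cfg is not None:
        d = distances(net, output_cfg.sensed_nodes, "reverse")
        sides.append(max((INF if v is UNREACHABLE else v) for v in d.values()))
    return float(max(sides))


def system_measures(net: DirectedNetwork,
                    input_cfg: InputConfiguration,
                    output_cfg: OutputConfiguration) -> SystemMeasures:
    """Compute the system-level measure panel for a configured network."""
    n, e = net.n_nodes, net.n_edges
    model = build_model(net, input_cfg, output_cfg)
    connected, symmetric, loops = edge_pair_counts(net)

    # diameter: longest finite directed shortest path
    diam = 0.0
    for v in net.labels:
        diam = max(diam, _finite_max(distances(net, [v], "forward").values()))

    degrees = np.array([net.total_degree(v) for v in net.labels], dtype=float)
    d_max = degrees.max() if n else 0.0
    freeman = (float((d_max - degrees).sum() / ((n - 1) * (n - 2)))
               if n > 2 else 0.0)

    in_deg = {v: net.in_degree(v) for v in net.labels}
    out_deg = {v: net.out_degree(v) for v in net.labels}
    edges = sorted(net.edges, key=lambda uv: (_sort_key(uv[0]), _sort_key(uv[1])))
    pear = {}
    for a, adeg in (("in", in_deg), ("out", out_deg)):
        for b, bdeg in (("in", in_deg), ("out", out_deg)):
            pear[f"{a}_{b}"] = _pearson([adeg[u] for u, _ in edges],
                                        [bdeg[v] for _, v in edges])

    return SystemMeasures(
        controllability=int(structural_controllability_test(model)),
        observability=int(structural_observability_test(model)),
        n_nodes=n,
        n_edges=e,
        density=e / n**2 if n else 0.0,
        diameter=diam,
        freeman_centrality=freeman,
        degree_variance=float(degrees.var()) if n else 0.0,
        relative_degree=relative_degree(net, input_cfg, output_cfg),
        pearson_in_in=pear["in_in"],
        pearson_in_out=pear["in_out"],
        pearson_out_out=pear["out_out"],
        pearson_out_in=pear["out_in"],
        percent_loops=100.0 * loops / e if e else 0.0,
        percent_sym=100.0 * symmetric / connected if connected else 0.0,
    )


# -- node measures ---------------------------------------------------------

def _reach_sets(net: DirectedNetwork, direction: str) -> dict[Node, set[Node]]:
    return {
        v: {u for u, d in distances(net, [v], direction).items() if d is not UNREACHABLE}
        for v in net.labels
    }


def node_measures(net: DirectedNetwork,
                  input_cfg: InputConfiguration | None = None,
                  output_cfg: OutputConfiguration | None = None) -> pd.DataFrame:
    """Per-node measure table, indexed by node label.

    Columns: in/out/total degree, scott (degree / (N-1)), closeness
    (|reachable| / sum of distances), betweenness, pagerank,
    neighbor_correlation (mean total degree of out-neighbours),
    control_centrality (forward-reachable set size incl. self),
    observe_centrality (backward dual), and node_class for configured
    drivers/sensors (empty string otherwise).
    """
    g = net.to_networkx()
    n = net.n_nodes
    betw = nx.betweenness_centrality(g, normalized=False) if n > 2 else dict.fromkeys(net.labels, 0.0)
    pr = nx.pagerank(g, alpha=0.85, tol=1e-12 / max(n, 1), max_iter=1000)

    rows = []
    for v in net.labels:
        fwd = distances(net, [v], "forward")
        reach = {u: d for u, d in fwd.items() if d is not UNREACHABLE and u != v}
        closeness = len(reach) / sum(reach.values()) if reach and sum(reach.values()) else 0.0
        out_nbrs = net.successors(v)
        ncorr = (sum(net.total_degree(u) for u in out_nbrs) / len(out_nbrs)
                 if out_nbrs else 0.0)
        bwd = distances(net, [v], "reverse")
        rows.append({
            "node": v,
            "in_degree": net.in_degree(v),
            "out_degree": net.out_degree(v),
            "total_degree": net.total_degree(v),
            "scott": net.total_degree(v) / (n - 1) if n > 1 else 0.0,
            "closeness": closeness,
            "betweenness": float(betw[v]),
            "pagerank": float(pr[v]),
            "neighbor_correlation": ncorr,
            "control_centrality": sum(1 for d in fwd.values() if d is not UNREACHABLE),
            "observe_centrality": sum(1 for d in bwd.values() if d is not UNREACHABLE),
        })
    table = pd.DataFrame(rows).set_index("node")

    table["node_class"] = ""
    if input_cfg is not None:
        for v, cls in classify_config_nodes(net, input_cfg.actuated_nodes).items():
            table.loc[[v], "node_class"] = cls
    if output_cfg is not None:
        rev = net.reverse()
        for v, cls in classify_config_nodes(rev, output_cfg.sensed_nodes).items():
            prev = table.loc[v, "node_class"]
            table.loc[[v], "node_class"] = prev + ("|" if prev else "") + cls
    return table


def classify_config_nodes(net: DirectedNetwork, nodes: set[Node]) -> dict[Node, str]:
    """Classify each configured driver node by why it needs a dedicated input.

    * ``source`` — no incoming edge;
    * ``external_dilation`` — part of a dilation and a leaf (no outgoing edge);
    * ``internal_dilation`` — part of a dilation with outgoing edges;
    * ``inaccessible`` — has incoming edges and no dilation, but no directed
      path reaches it from any other configured node.

    Sensors are classified by calling this on the reversed network.
    """
    for v in nodes:
        if v not in net:
            raise ValueError(f"node {v!r} not in network")
    out: dict[Node, str] = {}
    for v in sorted(nodes, key=_sort_key):
        if net.in_degree(v) == 0:
            out[v] = "source"
            continue
        others = set(nodes) - {v}
        reachable = False
        if others:
            d = distances(net, others, "forward")
            reachable = d[v] is not UNREACHABLE
        if reachable:
            out[v] = "external_dilation" if net.out_degree(v) == 0 else "internal_dilation"
        else:
            out[v] = "inaccessible"
    return out


# -- controlling / observing matrices and similarity ----------------------

def controlling_matrix(net: DirectedNetwork,
                       input_cfg: InputConfiguration) -> pd.DataFrame:
    """N x N sparse distance matrix: entry (i, j) is defined only for driver
    columns j and holds the hop distance from driver j to node i (0 on the
    driver's own row); ``inf`` marks unreachable.  The row-minimum over
    driver columns is the node's relative degree (number of derivations
    needed to influence that state)."""
    mat = pd.DataFrame(INF, index=net.labels, columns=net.labels, dtype=float)
    for j in sorted(input_cfg.actuated_nodes, key=_sort_key):
        d = distances(net, [j], "forward")
        for i in net.labels:
            mat.loc[i, j] = INF if d[i] is UNREACHABLE else float(d[i])
    non_drivers = [c for c in net.labels if c not in input_cfg.actuated_nodes]
    mat[non_drivers] = np.nan
    return mat


def observing_matrix(net: DirectedNetwork,
                     output_cfg: OutputConfiguration) -> pd.DataFrame:
    """Dual of :func:`controlling_matrix` on the reversed network."""
    dual_cfg = InputConfiguration(driver_nodes=output_cfg.sensor_nodes,
                                  assignment=dict(output_cfg.assignment),
                                  method=output_cfg.method)
    return controlling_matrix(net.reverse(), dual_cfg)


def node_relative_degrees(matrix: pd.DataFrame) -> pd.Series:
    """Row minima of a controlling/observing matrix (per-node relative degree)."""
    return matrix.min(axis=1, skipna=True)


def mean_relative_degree(matrix: pd.DataFrame) -> float:
    """Mean over all N nodes of the per-node relative degree."""
    return float(node_relative_degrees(matrix).mean())


def config_relative_degree_stats(net: DirectedNetwork, nodes: set[Node],
                                 direction: str = "forward") -> tuple[float, float]:
    """(max, mean) hop distance from the placed set, over all nodes."""
    d = distances(net, nodes, direction)
    vals = [INF if x is UNREACHABLE else float(x) for x in d.values()]
    return max(vals), sum(vals) / len(vals)


def reachability_matrices(net: DirectedNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(R_c, R_o): boolean transitive closures with a true diagonal.

    Row i of R_c lists the nodes reachable from node i (those it can
    control, in the reachability sense); column i lists the nodes that can
    control node i.  R_o is the transpose, read analogously for observation.
    """
    fwd = _reach_sets(net, "forward")
    rc = pd.DataFrame(False, index=net.labels, columns=net.labels, dtype=bool)
    for v, reach in fwd.items():
        rc.loc[v, sorted(reach, key=_sort_key)] = True
        rc.loc[v, v] = True
    return rc, rc.T.copy()


def driver_similarity(net: DirectedNetwork,
                      input_cfg: InputConfiguration) -> pd.DataFrame:
    """Pairwise similarity of driver nodes: the fraction of nodes both
    drivers reach at the *same* hop distance, among nodes either reaches.
    The diagonal is 1 by convention."""
    drivers = sorted(input_cfg.actuated_nodes, key=_sort_key)
    dists = {a: distances(net, [a], "forward") for a in drivers}
    sim = pd.DataFrame(0.0, index=drivers, columns=drivers, dtype=float)
    for a in drivers:
        for b in drivers:
            if a == b:
                sim.loc[a, b] = 1.0
                continue
            da, db = dists[a], dists[b]
            agree = sum(1 for v in net.labels
                        if da[v] is not UNREACHABLE and da[v] == db[v])
            union = sum(1 for v in net.labels
                        if da[v] is not UNREACHABLE or db[v] is not UNREACHABLE)
            sim.loc[a, b] = agree / union if union else 0.0
    return sim


def sensor_similarity(net: DirectedNetwork,
                      output_cfg: OutputConfiguration) -> pd.DataFrame:
    dual_cfg = InputConfiguration(driver_nodes=output_cfg.sensor_nodes,
                                  assignment=dict(output_cfg.assignment),
                                  method=output_cfg.method)
    return driver_similarity(net.reverse(), dual_cfg)


# -- edge measures ---------------------------------------------------------

def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 1.0


def _shortest_path_pairs_using_edges(net: DirectedNetwork) -> dict[tuple, set]:
    """For each edge, the set of ordered node pairs (s, t), s != t, with at
    least one shortest s->t path traversing the edge.

    Edge u->v lies on a shortest s->t path iff d(s,u) + 1 + d(v,t) = d(s,t).
    """
    sssp = {v: distances(net, [v], "forward") for v in net.labels}
    using: dict[tuple, set] = {e: set() for e in net.edges}
    for (u, v) in net.edges:
        if u == v:
            continue
        dist_v = sssp[v]
        for s in net.labels:
            dist_s = sssp[s]
            if dist_s[u] is UNREACHABLE:
                continue
            for t in net.labels:
                if t == s or dist_s[t] is UNREACHABLE or dist_v[t] is UNREACHABLE:
                    continue
                if dist_s[t] == dist_s[u] + 1 + dist_v[t]:
                    using[(u, v)].add((s, t))
    return using


@dataclass
class EdgeMeasureTable:
    """Per-edge measures plus the pairwise edge-similarity matrix."""

    table: pd.DataFrame           # index: edge tuples; betweenness, endpoint_similarity
    edge_similarity: pd.DataFrame  # E x E Jaccard of served (s, t) pairs


def edge_measures(net: DirectedNetwork) -> EdgeMeasureTable:
    """Edge betweenness (directed fractional shortest-path counting),
    endpoint similarity (mean Jaccard of the endpoints' forward- and
    backward-reachable sets, node included), and pairwise edge similarity
    (Jaccard of the source-target pairs whose shortest paths use each edge).
    """
    g = net.to_networkx()
    betw = nx.edge_betweenness_centrality(g, normalized=False)
    fwd = _reach_sets(net, "forward")
    bwd = _reach_sets(net, "reverse")
    edges = sorted(net.edges, key=lambda uv: (_sort_key(uv[0]), _sort_key(uv[1])))
    rows = []
    for (u, v) in edges:
        endpoint_sim = 0.5 * (_jaccard(fwd[u], fwd[v]) + _jaccard(bwd[u], bwd[v]))
        rows.append({"edge": (u, v),
                     "betweenness": float(betw.get((u, v), 0.0)),
                     "endpoint_similarity": endpoint_sim})
    table = pd.DataFrame(rows).set_index("edge")

    using = _shortest_path_pairs_using_edges(net)
    idx = pd.Index(edges, tupleize_cols=False)
    sim = pd.DataFrame(0.0, index=idx, columns=idx, dtype=float)
    for e in edges:
        for f in edges:
            sim.loc[[e], [f]] = _jaccard(using[e], using[f])
    return EdgeMeasureTable(table=table, edge_similarity=sim)
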