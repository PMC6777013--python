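"""Improve driver/sensor placement under a relative-degree requirement.

Given a required relative degree ``r``, every state must be within ``r``
hops (forward from a driver, or backward to a sensor).  Five methods are
provided:

* ``setcov_grassroot`` — greedy set cover over distance-``r`` balls, ignoring
  the minimal configuration (controllability/observability NOT guaranteed);
* ``setcov_retrofit`` — greedy cover starting from the minimal driver/sensor
  set, so structural controllability/observability is preserved;
* ``centmeas_retrofit`` — retrofit guided by closeness centrality instead of
  marginal coverage;
* ``mclasa`` — k-medoid search with simulated annealing on the placement
  cost, the minimal configuration held as mandatory medoids;
* ``gdfcmsa`` — the same search with the assignment term fuzzified by
  c-medoid memberships (fuzzifier m = 2).

Placement quality is the cost ``alpha * r_achieved + (1 - alpha) * mean
relative degree``: ``alpha`` trades the worst-case response distance against
the average one.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Hashable

from .graph_core import (
    DirectedNetwork,
    UNREACHABLE,
    _sort_key,
    distances,
    minimal_driver_nodes,
    minimal_sensor_nodes,
)

Node = Hashable

METHODS = ("setcov_grassroot", "setcov_retrofit", "centmeas_retrofit",
           "mclasa", "gdfcmsa")

INF = math.inf


@dataclass
class ImprovementConfig:
    """Parameters of an improvement run.

    ``required_relative_degree`` (hops, >= 0) is the coverage radius;
    ``alpha`` in [0, 1] weighs worst-case against mean relative degree in
    the cost; the SA parameters control the annealing schedule of the
    medoid-based methods (initial temperature, geometric cooling factor,
    iterations per medoid count).
    """

    required_relative_degree: int = 2
    alpha: float = 0.5
    method: str = "setcov_retrofit"
    seed: int = 0
    sa_initial_temperature: float = 1.0
    sa_cooling: float = 0.95
    sa_iterations: int = 500

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.required_relative_degree < 0:
            raise ValueError("required relative degree must be >= 0")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (0 < self.sa_cooling < 1) or self.sa_initial_temperature <= 0 \
                or self.sa_iterations < 1:
            raise ValueError("invalid simulated-annealing parameters")


@dataclass
class ImprovementResult:
    """Placement returned by an improvement method."""

    nodes: set[Node]
    n_placed: int
    relative_degree: float
    mean_relative_degree: float
    cost: float
    method: str
    seed: int | None = None
    side: str = "input"

    def to_dict(self) -> dict:
        return {
            "nodes": sorted(self.nodes, key=_sort_key),
            "n_placed": self.n_placed,
            "relative_degree": self.relative_degree,
            "mean_relative_degree": self.mean_relative_degree,
            "cost": self.cost,
            "method": self.method,
            "seed": self.seed,
            "side": self.side,
        }


def placement_cost(r_achieved: float, mean_rd: float, alpha: float) -> float:
    """Cost of a placement: ``alpha * r_achieved + (1 - alpha) * mean_rd``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * r_achieved + (1.0 - alpha) * mean_rd


def _stats(net: DirectedNetwork, nodes: set[Node],
           direction: str) -> tuple[float, float]:
    """(max, mean) hop distance from the placed set over all N nodes."""
    d = distances(net, nodes, direction)
    vals = [INF if x is UNREACHABLE else float(x) for x in d.values()]
    return max(vals), sum(vals) / len(vals)


def _result(net: DirectedNetwork, nodes: set[Node], cfg: ImprovementConfig,
            direction: str, side: str, seed: int | None = None) -> ImprovementResult:
    r_ach, mean_rd = _stats(net, nodes, direction)
    return ImprovementResult(
        nodes=set(nodes),
        n_placed=len(nodes),
        relative_degree=r_ach,
        mean_relative_degree=mean_rd,
        cost=placement_cost(r_ach, mean_rd, cfg.alpha),
        method=cfg.method,
        seed=seed,
        side=side,
    )


def _balls(net: DirectedNetwork, r: int, direction: str) -> dict[Node, set[Node]]:
    """ball(v) = set of nodes within r hops of v (forward or reverse)."""
    return {
        v: {u for u, d in distances(net, [v], direction).items()
            if d is not UNREACHABLE and d <= r}
        for v in net.labels
    }


def _greedy_cover(net: DirectedNetwork, r: int, direction: str,
                  initial: set[Node]) -> set[Node]:
    """Greedy set cover: repeatedly add the node whose ball covers the most
    still-uncovered nodes, ties to the smallest label."""
    balls = _balls(net, r, direction)
    chosen = set(initial)
    covered = set()
    for v in chosen:
        covered |= balls[v]
    uncovered = set(net.labels) - covered
    order = sorted(net.labels, key=_sort_key)
    while uncovered:
        best = max(order, key=lambda v: len(balls[v] & uncovered))
        # every node covers itself (distance 0), so progress is guaranteed
        chosen.add(best)
        uncovered -= balls[best]
    return chosen


def _closeness(net: DirectedNetwork, direction: str) -> dict[Node, float]:
    out = {}
    for v in net.labels:
        d = distances(net, [v], direction)
        reach = {u: x for u, x in d.items() if x is not UNREACHABLE and u != v}
        total = sum(reach.values())
        out[v] = len(reach) / total if total else 0.0
    return out


def _side(sensors: bool) -> tuple[str, str]:
    """(BFS direction, result side tag) for driver vs sensor placement."""
    return ("reverse", "output") if sensors else ("forward", "input")


def setcov_grassroot(net: DirectedNetwork, cfg: ImprovementConfig,
                     sensors: bool = False) -> ImprovementResult:
    """Greedy set cover from scratch; satisfies the coverage radius but does
    not account for the minimal configuration, so structural
    controllability/observability is *not* guaranteed."""
    direction, side = _side(sensors)
    nodes = _greedy_cover(net, cfg.required_relative_degree, direction, set())
    return _result(net, nodes, cfg, direction, side)


def setcov_retrofit(net: DirectedNetwork, cfg: ImprovementConfig,
                    sensors: bool = False) -> ImprovementResult:
    """Greedy set cover extending the minimal driver (sensor) set, so the
    structural guarantee of the minimal configuration is preserved."""
    direction, side = _side(sensors)
    minimal = minimal_sensor_nodes(net) if sensors else minimal_driver_nodes(net)
    nodes = _greedy_cover(net, cfg.required_relative_degree, direction, minimal)
    return _result(net, nodes, cfg, direction, side)


def centmeas_retrofit(net: DirectedNetwork, cfg: ImprovementConfig,
                      sensors: bool = False) -> ImprovementResult:
    """Retrofit guided by closeness: while uncovered nodes remain, add the
    highest-closeness node whose ball covers at least one of them."""
    direction, side = _side(sensors)
    minimal = minimal_sensor_nodes(net) if sensors else minimal_driver_nodes(net)
    balls = _balls(net, cfg.required_relative_degree, direction)
    closeness = _closeness(net, direction)
    chosen = set(minimal)
    uncovered = set(net.labels)
    for v in chosen:
        uncovered -= balls[v]
    order = sorted(net.labels, key=_sort_key)
    while uncovered:
        candidates = [v for v in order if balls[v] & uncovered]
        best = max(candidates, key=lambda v: closeness[v])
        chosen.add(best)
        uncovered -= balls[best]
    return _result(net, chosen, cfg, direction, side)


# -- simulated-annealing medoid search -------------------------------------

def _assignment_cost(net: DirectedNetwork, medoids: set[Node], direction: str,
                     alpha: float, fuzzy: bool, penalty: float,
                     sssp: dict[Node, dict[Node, int | None]]) -> float:
    """SA objective: alpha-weighted worst-case distance plus (fuzzy) mean
    assignment distance; unreachable nodes incur the penalty distance."""
    dmat = {}
    for v in net.labels:
        row = []
        for j in medoids:
            d = sssp[j][v]
            row.append(penalty if d is UNREACHABLE else float(d))
        dmat[v] = row
    r_ach = max(min(row) for row in dmat.values())
    if not fuzzy:
        mean = sum(min(row) for row in dmat.values()) / net.n_nodes
    else:
        # fuzzy c-medoid memberships, fuzzifier m = 2: u_ij = 1 / sum_k (d_ij/d_ik)^2
        total = 0.0
        for row in dmat.values():
            if min(row) == 0.0:
                continue  # crisp assignment to a zero-distance medoid
            for d_ij in row:
                u = 1.0 / sum((d_ij / d_ik) ** 2 for d_ik in row)
                total += (u ** 2) * d_ij
        mean = total / net.n_nodes
    return placement_cost(r_ach, mean, alpha)


def _sa_medoids(net: DirectedNetwork, cfg: ImprovementConfig, sensors: bool,
                fuzzy: bool) -> ImprovementResult:
    direction, side = _side(sensors)
    mandatory = minimal_sensor_nodes(net) if sensors else minimal_driver_nodes(net)
    r = cfg.required_relative_degree
    rng = random.Random(cfg.seed)
    penalty = float(net.n_nodes)
    sssp = {v: distances(net, [v], direction) for v in net.labels}
    pool_all = sorted(set(net.labels) - mandatory, key=_sort_key)

    def feasible(nodes: set[Node]) -> bool:
        return _stats(net, nodes, direction)[0] <= r

    def objective(nodes: set[Node]) -> float:
        return _assignment_cost(net, nodes, direction, cfg.alpha, fuzzy,
                                penalty, sssp)

    best_feasible: set[Node] | None = None
    if feasible(mandatory):
        best_feasible = set(mandatory)
    k_free = 0
    while best_feasible is None and k_free < len(pool_all):
        k_free += 1
        free = set(rng.sample(pool_all, k_free))
        current = mandatory | free
        cur_obj = objective(current)
        temp = cfg.sa_initial_temperature
        best_cost = INF
        if feasible(current):
            r_ach, mean_rd = _stats(net, current, direction)
            best_cost = placement_cost(r_ach, mean_rd, cfg.alpha)
            best_feasible = set(current)
        for _ in range(cfg.sa_iterations):
            inside = sorted(current - mandatory, key=_sort_key)
            outside = sorted(set(pool_all) - current, key=_sort_key)
            if not inside or not outside:
                break
            out_node = rng.choice(inside)
            in_node = rng.choice(outside)
            proposal = (current - {out_node}) | {in_node}
            prop_obj = objective(proposal)
            if prop_obj <= cur_obj or rng.random() < math.exp((cur_obj - prop_obj) / temp):
                current, cur_obj = proposal, prop_obj
            if feasible(current):
                r_ach, mean_rd = _stats(net, current, direction)
                cost = placement_cost(r_ach, mean_rd, cfg.alpha)
                if cost < best_cost:
                    best_cost = cost
                    best_feasible = set(current)
            temp *= cfg.sa_cooling
        # k_free increments until a feasible set is found; k = N is always
        # feasible (every node its own medoid, all distances 0)
    if best_feasible is None:
        best_feasible = set(net.labels)
    return _result(net, best_feasible, cfg, direction, side, seed=cfg.seed)


def mclasa(net: DirectedNetwork, cfg: ImprovementConfig,
           sensors: bool = False) -> ImprovementResult:
    """k-medoid placement by simulated annealing on the placement cost, the
    minimal configuration held as mandatory medoids; the medoid count grows
    until the coverage radius is met."""
    return _sa_medoids(net, cfg, sensors, fuzzy=False)


def gdfcmsa(net: DirectedNetwork, cfg: ImprovementConfig,
            sensors: bool = False) -> ImprovementResult:
    """Geodesic fuzzy c-medoid variant of :func:`mclasa`: the assignment
    term of the annealing objective is weighted by fuzzy memberships
    (fuzzifier m = 2); zero-distance nodes are assigned crisply."""
    return _sa_medoids(net, cfg, sensors, fuzzy=True)


_DISPATCH = {
    "setcov_grassroot": setcov_grassroot,
    "setcov_retrofit": setcov_retrofit,
    "centmeas_retrofit": centmeas_retrofit,
    "mclasa": mclasa,
    "gdfcmsa": gdfcmsa,
}


def improve(net: DirectedNetwork, cfg: ImprovementConfig,
            sensors: bool = False) -> ImprovementResult:
    """Dispatch to the configured improvement method."""
    return _DISPATCH[cfg.method](net, cfg, sensors=sensors)
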