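"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own algorithms: matching size
by exhaustive branch-and-bound over edge subsets, betweenness/closeness by
explicit shortest-path enumeration through networkx path generators.
"""

from __future__ import annotations

import networkx as nx
import pytest

from ctrlnet import DirectedNetwork
from ctrlnet.fixtures import chain, cycle, erdos_renyi_directed, star


def brute_force_matching_size(net: DirectedNetwork) -> int:
    """Maximum number of pairwise disjoint edges, by exhaustive search."""
    edges = sorted(net.edges, key=lambda e: (str(e[0]), str(e[1])))
    best = 0

    def rec(i: int, used_out: frozenset, used_in: frozenset, size: int) -> None:
        nonlocal best
        best = max(best, size)
        if size + (len(edges) - i) <= best:
            return
        for j in range(i, len(edges)):
            u, v = edges[j]
            if u not in used_out and v not in used_in:
                rec(j + 1, used_out | {u}, used_in | {v}, size + 1)

    rec(0, frozenset(), frozenset(), 0)
    return best


def betweenness_by_path_enumeration(net: DirectedNetwork) -> dict:
    """Node betweenness from explicit all-shortest-path listings."""
    g = net.to_networkx()
    scores = dict.fromkeys(net.labels, 0.0)
    for s in net.labels:
        for t in net.labels:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in net.labels:
                if v in (s, t):
                    continue
                hits = sum(1 for p in paths if v in p)
                scores[v] += hits / len(paths)
    return scores


def edge_betweenness_by_path_enumeration(net: DirectedNetwork) -> dict:
    g = net.to_networkx()
    scores = {e: 0.0 for e in net.edges}
    for s in net.labels:
        for t in net.labels:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for e in net.edges:
                hits = sum(1 for p in paths
                           if e in zip(p, p[1:]))
                scores[e] += hits / len(paths)
    return scores


def closeness_by_bfs(net: DirectedNetwork) -> dict:
    g = net.to_networkx()
    out = {}
    for v in net.labels:
        lengths = nx.single_source_shortest_path_length(g, v)
        lengths.pop(v, None)
        total = sum(lengths.values())
        out[v] = len(lengths) / total if total else 0.0
    return out


@pytest.fixture
def chain3() -> DirectedNetwork:
    return chain(3)


@pytest.fixture
def chain5() -> DirectedNetwork:
    return chain(5)


@pytest.fixture
def cycle3() -> DirectedNetwork:
    return cycle(3)


@pytest.fixture
def star2() -> DirectedNetwork:
    """Centre 1 pointing at leaves 2 and 3 (a two-fold dilation)."""
    return star(2)


def random_nets(n_instances: int, n_max: int, p: float = 0.3, seed0: int = 0):
    """Deterministic stream of small random digraphs of varying size."""
    nets = []
    for i in range(n_instances):
        n = 2 + (i % (n_max - 1))
        nets.append(erdos_renyi_directed(n, p, seed=seed0 + i))
    return nets
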