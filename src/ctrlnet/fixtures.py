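"""Seeded synthetic directed-network generators for testing and examples.

Each generator is deterministic given its parameters (and seed, where it
uses randomness) and guarantees an advertised structural property:
``reciprocal_pairs`` has a perfect maximum matching by construction (every
node is matched within its mutual pair, the regime of reciprocally coupled
command interneurons), and ``scc_mosaic`` realises a prescribed condensation
DAG over cycle components (the regime where input-placement strategies can
diverge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import DirectedNetwork

GENERATORS = ("chain", "cycle", "star", "reciprocal_pairs", "scc_mosaic",
              "erdos_renyi_directed")


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic network."""

    generator: str
    n: int = 0
    p: float = 0.2            # edge probability (erdos_renyi_directed)
    cross: int = 0            # extra cross edges (reciprocal_pairs)
    cycle_sizes: tuple[int, ...] = ()      # scc_mosaic component sizes
    dag_edges: tuple[tuple[int, int], ...] = ()  # scc_mosaic condensation edges
    seed: int = 0

    def __post_init__(self):
        if self.generator not in GENERATORS:
            raise ValueError(f"unknown generator {self.generator!r}")


def chain(n: int) -> DirectedNetwork:
    """Directed path 1 -> 2 -> ... -> n."""
    if n < 1:
        raise ValueError("chain needs n >= 1")
    labels = list(range(1, n + 1))
    return DirectedNetwork(labels, [(i, i + 1) for i in range(1, n)])


def cycle(n: int) -> DirectedNetwork:
    """Directed cycle 1 -> 2 -> ... -> n -> 1."""
    if n < 1:
        raise ValueError("cycle needs n >= 1")
    labels = list(range(1, n + 1))
    edges = [(i, i + 1) for i in range(1, n)] + [(n, 1)]
    return DirectedNetwork(labels, edges)


def star(n_leaves: int) -> DirectedNetwork:
    """Centre 1 pointing at leaves 2..n_leaves+1 (an n_leaves-fold dilation)."""
    if n_leaves < 1:
        raise ValueError("star needs at least one leaf")
    labels = list(range(1, n_leaves + 2))
    return DirectedNetwork(labels, [(1, leaf) for leaf in labels[1:]])


def reciprocal_pairs(n: int, cross: int = 0, seed: int = 0) -> DirectedNetwork:
    """n/2 mutually coupled node pairs plus ``cross`` seeded one-way edges.

    The mutual edges alone form a perfect matching (each node matched within
    its pair), so the minimal driver set collapses to a single fallback node
    regardless of the cross edges.
    """
    if n < 2 or n % 2:
        raise ValueError("reciprocal_pairs needs an even n >= 2")
    labels = list(range(1, n + 1))
    edges = set()
    for a in range(1, n + 1, 2):
        edges.add((a, a + 1))
        edges.add((a + 1, a))
    rng = np.random.default_rng(seed)
    attempts = 0
    placed = 0
    while placed < cross and attempts < 100 * max(cross, 1):
        u, v = (int(x) for x in rng.integers(1, n + 1, size=2))
        attempts += 1
        if u != v and (u, v) not in edges:
            edges.add((u, v))
            placed += 1
    return DirectedNetwork(labels, edges)


def scc_mosaic(cycle_sizes: tuple[int, ...],
               dag_edges: tuple[tuple[int, int], ...] = ()) -> DirectedNetwork:
    """Cycles joined into a prescribed condensation DAG.

    ``cycle_sizes[i]`` is the length of component i; ``dag_edges`` are
    component-index pairs (i, j) realised as one edge from the first node of
    cycle i to the first node of cycle j.  The condensation of the result is
    exactly the given DAG.
    """
    if not cycle_sizes or any(s < 1 for s in cycle_sizes):
        raise ValueError("cycle sizes must be positive")
    starts = []
    labels: list[int] = []
    nxt = 1
    for size in cycle_sizes:
        starts.append(nxt)
        labels.extend(range(nxt, nxt + size))
        nxt += size
    edges = set()
    for start, size in zip(starts, cycle_sizes):
        if size == 1:
            edges.add((start, start))  # self-loop keeps the single node an SCC on a cycle
        else:
            for k in range(size - 1):
                edges.add((start + k, start + k + 1))
            edges.add((start + size - 1, start))
    for i, j in dag_edges:
        if i == j or not (0 <= i < len(cycle_sizes)) or not (0 <= j < len(cycle_sizes)):
            raise ValueError("dag edges must join distinct valid components")
        edges.add((starts[i], starts[j]))
    return DirectedNetwork(labels, edges)


def erdos_renyi_directed(n: int, p: float, seed: int = 0) -> DirectedNetwork:
    """G(n, p) digraph with independent directed edges, no self-loops."""
    if n < 1 or not 0.0 <= p <= 1.0:
        raise ValueError("need n >= 1 and p in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    labels = list(range(1, n + 1))
    rows, cols = np.nonzero(mask)
    return DirectedNetwork(labels, [(labels[i], labels[j]) for i, j in zip(rows, cols)])


def generate(spec: FixtureSpec) -> DirectedNetwork:
    """Materialise a :class:`FixtureSpec`."""
    if spec.generator == "chain":
        return chain(spec.n)
    if spec.generator == "cycle":
        return cycle(spec.n)
    if spec.generator == "star":
        return star(spec.n)
    if spec.generator == "reciprocal_pairs":
        return reciprocal_pairs(spec.n, spec.cross, spec.seed)
    if spec.generator == "scc_mosaic":
        return scc_mosaic(spec.cycle_sizes, spec.dag_edges)
    return erdos_renyi_directed(spec.n, spec.p, spec.seed)
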