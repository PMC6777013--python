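"""Core data model and structural-control machinery for directed networks.

A directed network with adjacency convention ``M[i][j] = 1 iff edge i -> j``
is viewed as a linear time-invariant system

    dx/dt = A x + B u,      y = C x + D u

whose state matrix pattern ``A`` is the *transpose* of the network adjacency
matrix: an edge ``u -> v`` means state ``u`` drives state ``v``, i.e.
``A[v][u] = 1``.  Structural controllability is decided graph-theoretically
(accessibility from the actuated states plus a dilation-free condition via
bipartite matching), which by Lin's structural controllability theorem is
equivalent to the Kalman controllability matrix ``[B, AB, ..., A^{N-1}B]``
having generic rank ``N``.  A randomized exact-arithmetic rank oracle over a
prime field is provided to cross-check the graph-theoretic test on small
systems.

Driver (sensor) nodes are the unmatched nodes of a maximum matching of the
bipartite out-copy/in-copy graph: a maximum set of edges no two of which
share a starting point or an endpoint.  Matching ties are broken by
processing nodes in ascending label order so results are reproducible even
though maximum matchings are not unique.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

Node = Hashable
Edge = tuple[Node, Node]

#: Marker returned by :func:`distances` for nodes with no directed path
#: from any source.
UNREACHABLE = None


def _sort_key(label: Node):
    """Total order over labels of possibly mixed types (ints before strings)."""
    return (isinstance(label, str), label)


class DirectedNetwork:
    """Node-labelled directed graph (the toolbox's network representation).

    Parameters
    ----------
    labels : sequence of hashables
        Unique node identifiers, in a fixed order that defines the
        adjacency-matrix indexing.
    edges : iterable of (u, v) pairs
        Directed edges ``u -> v``; multi-edges collapse, self-loops are kept.

    Notes
    -----
    Entry ``(i, j)`` of the adjacency matrix is 1 iff edge ``i -> j`` exists,
    so the adjacency matrix equals ``A.T`` of the associated state matrix.
    """

    def __init__(self, labels: Sequence[Node], edges: Iterable[Edge] = ()):
        self.labels: list[Node] = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")
        self._index: dict[Node, int] = {v: i for i, v in enumerate(self.labels)}
        self.edges: set[Edge] = set()
        for u, v in edges:
            if u not in self._index or v not in self._index:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown label")
            self.edges.add((u, v))
        self._succ: dict[Node, list[Node]] = {v: [] for v in self.labels}
        self._pred: dict[Node, list[Node]] = {v: [] for v in self.labels}
        for u, v in sorted(self.edges, key=lambda e: (_sort_key(e[0]), _sort_key(e[1]))):
            self._succ[u].append(v)
            self._pred[v].append(u)

    # -- basic protocol ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, label: Node) -> bool:
        return label in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DirectedNetwork)
            and self.labels == other.labels
            and self.edges == other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def index(self, label: Node) -> int:
        return self._index[label]

    def successors(self, label: Node) -> list[Node]:
        """Out-neighbours in ascending label order."""
        return self._succ[label]

    def predecessors(self, label: Node) -> list[Node]:
        return self._pred[label]

    def in_degree(self, label: Node) -> int:
        return len(self._pred[label])

    def out_degree(self, label: Node) -> int:
        return len(self._succ[label])

    def total_degree(self, label: Node) -> int:
        return len(self._pred[label]) + len(self._succ[label])

    # -- conversions ---------------------------------------------------

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix, ``M[i, j] = 1`` iff edge i -> j."""
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for u, v in self.edges:
            m[self._index[u], self._index[v]] = 1
        return m

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_adjacency(cls, matrix, labels: Sequence[Node] | None = None) -> "DirectedNetwork":
        """Build from a (dense or sparse) adjacency matrix; nonzero = edge."""
        if sparse.issparse(matrix):
            matrix = matrix.toarray()
        matrix = np.asarray(matrix)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("adjacency matrix must be square")
        n = matrix.shape[0]
        if labels is None:
            labels = list(range(1, n + 1))
        if len(labels) != n:
            raise ValueError("label count does not match matrix size")
        labels = list(labels)
        rows, cols = np.nonzero(matrix)
        edges = [(labels[i], labels[j]) for i, j in zip(rows, cols)]
        return cls(labels, edges)

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        return cls(list(g.nodes()), list(g.edges()))

    def reverse(self) -> "DirectedNetwork":
        """Network with every edge direction flipped."""
        return DirectedNetwork(self.labels, {(v, u) for u, v in self.edges})


@dataclass
class StateSpaceModel:
    """Sparsity patterns of an LTI system ``dx/dt = Ax + Bu``, ``y = Cx + Du``.

    ``A`` is N x N with ``A[v][u] = 1`` iff the network has edge u -> v;
    ``B`` is N x M (input k actuates state v iff ``B[v][k] = 1``); ``C`` is
    K x N (output k senses state v iff ``C[k][v] = 1``); ``D`` is the K x M
    feedthrough, all-zero by default.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray | None = None
    labels: list[Node] = field(default_factory=list)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.int8)
        self.B = np.asarray(self.B, dtype=np.int8)
        self.C = np.asarray(self.C, dtype=np.int8)
        n = self.A.shape[0]
        if self.A.ndim != 2 or self.A.shape[1] != n:
            raise ValueError("A must be square")
        if self.B.ndim != 2 or self.B.shape[0] != n:
            raise ValueError("B must have N rows")
        if self.C.ndim != 2 or self.C.shape[1] != n:
            raise ValueError("C must have N columns")
        if self.D is None:
            self.D = np.zeros((self.C.shape[0], self.B.shape[1]), dtype=np.int8)
        self.D = np.asarray(self.D, dtype=np.int8)
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise ValueError("D must be K x M")
        if not self.labels:
            self.labels = list(range(1, n + 1))
        if len(self.labels) != n:
            raise ValueError("label count does not match N")
        if self.B.shape[1] and (self.B.sum(axis=0) == 0).any():
            raise ValueError("every input column must actuate at least one state")
        if self.C.shape[0] and (self.C.sum(axis=1) == 0).any():
            raise ValueError("every output row must sense at least one state")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def network(self) -> DirectedNetwork:
        """Recover the network representation (adjacency = ``A.T``)."""
        return DirectedNetwork.from_adjacency(self.A.T, self.labels)

    def dual(self) -> "StateSpaceModel":
        """Observability dual: reversed graph, outputs become inputs."""
        return StateSpaceModel(self.A.T, self.C.T, self.B.T, None, list(self.labels))


@dataclass
class MatchingResult:
    """A maximum set of pairwise disjoint edges plus node bookkeeping.

    Two edges are disjoint when they share neither a starting point nor an
    endpoint; equivalently the edge set is a matching of the bipartite graph
    with one out-copy and one in-copy per node.
    """

    matched_edges: set[Edge]
    matched_nodes_in: set[Node]
    matched_nodes_out: set[Node]
    unmatched_in: set[Node]
    unmatched_out: set[Node]

    @property
    def size(self) -> int:
        return len(self.matched_edges)

    @property
    def is_perfect(self) -> bool:
        return not self.unmatched_in


def maximum_matching(net: DirectedNetwork) -> MatchingResult:
    """Maximum matching of the out-copy/in-copy bipartite graph.

    Augmenting-path (Kuhn) search processing out-copies in ascending label
    order, trying in-copies in ascending label order: deterministic matched
    sets even though the maximum matching itself is not unique.  The matching
    *size* is an invariant of the network.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    order = sorted(net.labels, key=_sort_key)
    match_in: dict[Node, Node] = {}   # in-copy -> out-copy
    match_out: dict[Node, Node] = {}  # out-copy -> in-copy

    def try_augment(u: Node, visited: set[Node]) -> bool:
        for v in net.successors(u):
            if v in visited:
                continue
            visited.add(v)
            if v not in match_in or try_augment(match_in[v], visited):
                match_in[v] = u
                match_out[u] = v
                return True
        return False

    for u in order:
        if net.out_degree(u):
            try_augment(u, set())

    matched_edges = {(u, v) for u, v in match_out.items()}
    matched_in = set(match_in)
    matched_out = set(match_out)
    all_nodes = set(net.labels)
    return MatchingResult(
        matched_edges=matched_edges,
        matched_nodes_in=matched_in,
        matched_nodes_out=matched_out,
        unmatched_in=all_nodes - matched_in,
        unmatched_out=all_nodes - matched_out,
    )


def scc_condensation(net: DirectedNetwork):
    """Strongly connected components and their acyclic condensation.

    Returns
    -------
    components : list of frozensets
        SCCs in a topological order of the condensation (sources first);
        ties broken by smallest member label.  Isolated nodes are their own
        components.
    dag : networkx.DiGraph
        Condensation DAG over component indices into ``components``.
    """
    g = net.to_networkx()
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    cond = nx.condensation(g, scc=comps)
    topo = list(nx.lexicographical_topological_sort(
        cond, key=lambda i: _sort_key(min(comps[i], key=_sort_key))))
    components = [comps[i] for i in topo]
    relabel = {old: new for new, old in enumerate(topo)}
    dag = nx.relabel_nodes(cond, relabel, copy=True)
    return components, dag


def source_components(net: DirectedNetwork) -> list[frozenset]:
    """Condensation components with no incoming condensation edge."""
    components, dag = scc_condensation(net)
    return [components[i] for i in range(len(components)) if dag.in_degree(i) == 0]


def sink_components(net: DirectedNetwork) -> list[frozenset]:
    components, dag = scc_condensation(net)
    return [components[i] for i in range(len(components)) if dag.out_degree(i) == 0]


def minimal_driver_nodes(net: DirectedNetwork) -> set[Node]:
    """Driver nodes: unmatched in-copies of a maximum matching.

    When the matching is perfect, structural controllability can be granted
    by actuating any single node; the deterministic fallback is the
    smallest-label node of the first source component in condensation
    topological order (this honours accessibility).
    """
    m = maximum_matching(net)
    if m.unmatched_in:
        return set(m.unmatched_in)
    first_source = source_components(net)[0]
    return {min(first_source, key=_sort_key)}


def minimal_sensor_nodes(net: DirectedNetwork) -> set[Node]:
    """Sensor nodes: unmatched out-copies (drivers of the reversed network)."""
    m = maximum_matching(net)
    if m.unmatched_out:
        return set(m.unmatched_out)
    first_sink = sink_components(net)[0]
    return {min(first_sink, key=_sort_key)}


def distances(net: DirectedNetwork, sources: Iterable[Node],
              direction: str = "forward") -> dict[Node, int | None]:
    """Multi-source directed BFS hop distances.

    Source nodes map to 0; nodes with no directed path from any source map
    to :data:`UNREACHABLE` (``None``).  ``direction="reverse"`` measures
    distance along reversed edges (i.e. distance *to* the sources).
    """
    sources = list(sources)
    for s in sources:
        if s not in net:
            raise ValueError(f"unknown source label {s!r}")
    if direction == "forward":
        step = net.successors
    elif direction == "reverse":
        step = net.predecessors
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    dist: dict[Node, int | None] = {v: UNREACHABLE for v in net.labels}
    queue = deque()
    for s in sorted(set(sources), key=_sort_key):
        dist[s] = 0
        queue.append(s)
    while queue:
        u = queue.popleft()
        for v in step(u):
            if dist[v] is UNREACHABLE:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


# -- structural tests ----------------------------------------------------

def _bipartite_saturates_states(A: np.ndarray, B: np.ndarray) -> bool:
    """True iff the bipartite graph (state out-copies + inputs) -> (state
    in-copies), with edges from the A and B patterns, has a matching
    saturating every state in-copy (no dilation)."""
    n, m = A.shape[0], B.shape[1]
    # left vertices: 0..n-1 state out-copies, n..n+m-1 inputs
    adj: list[list[int]] = [list(np.nonzero(A[:, u])[0]) for u in range(n)]
    adj += [list(np.nonzero(B[:, k])[0]) for k in range(m)]
    match_right = [-1] * n

    def try_augment(left: int, visited: list[bool]) -> bool:
        for r in adj[left]:
            if visited[r]:
                continue
            visited[r] = True
            if match_right[r] == -1 or try_augment(match_right[r], visited):
                match_right[r] = left
                return True
        return False

    matched = 0
    for left in range(n + m):
        if try_augment(left, [False] * n):
            matched += 1
            if matched == n:
                return True
    return matched == n


def structural_controllability_test(model: StateSpaceModel) -> bool:
    """Graph-theoretic structural controllability (Lin's theorem).

    True iff (accessibility) every state is reachable by a directed path
    from some actuated state and (no dilation) the bipartite graph built
    from the A and B patterns has a matching saturating all N states.
    Equivalent to the Kalman controllability matrix having generic rank N.
    """
    n = model.n_states
    if n == 0:
        raise ValueError("empty system")
    if model.n_inputs == 0:
        return False
    actuated = set(np.nonzero(model.B.sum(axis=1))[0])
    # accessibility: BFS over state graph u -> v iff A[v][u] = 1
    seen = set(actuated)
    queue = deque(actuated)
    succ = [list(np.nonzero(model.A[:, u])[0]) for u in range(n)]
    while queue:
        u = queue.popleft()
        for v in succ[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    if len(seen) < n:
        return False
    return _bipartite_saturates_states(model.A, model.B)


def structural_observability_test(model: StateSpaceModel) -> bool:
    """Dual test: observability of (A, C) = controllability of (A.T, C.T)."""
    return structural_controllability_test(model.dual())


# -- randomized exact-rank oracle ----------------------------------------

_ORACLE_PRIME = 2**31 - 1
_ORACLE_CAP = 64
_ORACLE_DRAWS = 3


def _rank_mod_p(mat: list[list[int]], p: int) -> int:
    """Exact rank of an integer matrix over GF(p) by Gaussian elimination."""
    mat = [row[:] for row in mat]
    n_rows = len(mat)
    n_cols = len(mat[0]) if n_rows else 0
    rank = 0
    col = 0
    while rank < n_rows and col < n_cols:
        pivot = next((r for r in range(rank, n_rows) if mat[r][col] % p), None)
        if pivot is None:
            col += 1
            continue
        mat[rank], mat[pivot] = mat[pivot], mat[rank]
        inv = pow(mat[rank][col], p - 2, p)
        mat[rank] = [(x * inv) % p for x in mat[rank]]
        for r in range(n_rows):
            if r != rank and mat[r][col] % p:
                f = mat[r][col] % p
                mat[r] = [(a - f * b) % p for a, b in zip(mat[r], mat[rank])]
        rank += 1
        col += 1
    return rank


def generic_rank_oracle(model: StateSpaceModel, seed: int = 0,
                        controllability: bool = True) -> int:
    """Generic rank of the Kalman matrix ``[B, AB, ..., A^{N-1}B]``.

    Substitutes independent random nonzero weights from GF(p), p = 2^31 - 1,
    into the nonzero patterns of A and B, computes the exact rank of the
    Kalman block matrix over the field, and takes the maximum over three
    seeded draws.  With overwhelming probability this equals the generic
    (structural) rank.  A testing oracle: capped at N <= 64; use the
    graph-theoretic structural test for larger systems.
    """
    if not controllability:
        return generic_rank_oracle(model.dual(), seed=seed, controllability=True)
    n, m = model.n_states, model.n_inputs
    if n > _ORACLE_CAP:
        raise ValueError(
            f"oracle capped at N <= {_ORACLE_CAP}; use structural_controllability_test")
    p = _ORACLE_PRIME
    best = 0
    for draw in range(_ORACLE_DRAWS):
        rng = np.random.default_rng((seed, draw))
        A = [[int(rng.integers(1, p)) if model.A[i, j] else 0 for j in range(n)]
             for i in range(n)]
        blk = [[int(rng.integers(1, p)) if model.B[i, k] else 0 for k in range(m)]
               for i in range(n)]
        kalman = [row[:] for row in blk]
        for _ in range(n - 1):
            blk = [[sum(A[i][j] * blk[j][k] for j in range(n) if A[i][j]) % p
                    for k in range(m)] for i in range(n)]
            for i in range(n):
                kalman[i].extend(blk[i])
        best = max(best, _rank_mod_p(kalman, p))
        if best == n:
            break
    return best
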