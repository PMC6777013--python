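# Methods

## Model and scope

`ctrlnet` analyses *structural* (generic) controllability and observability
of linear time-invariant systems given only the sparsity pattern of the
state matrix. A directed network with adjacency entry *(i, j)* = 1 iff edge
*i → j* defines `A = adjacencyᵀ` (`A[v][u] = 1` iff *u → v*); input and
output patterns B and C are placed by the package. The analysis is generic:
it holds for almost every numeric realisation of the pattern, and says
nothing about control energy or about nonlinear dynamics. Weighted and
temporal networks are out of scope; multi-edges collapse; self-loops are
kept and matter (a self-looped node is matched by its own loop).

Structural controllability is decided graph-theoretically as
*accessibility* (every state reachable by a directed path from an actuated
state) plus *no dilation* (the bipartite graph with left vertices = state
out-copies ∪ inputs, right vertices = state in-copies, and edges from the A
and B patterns admits a matching saturating all N states). Observability is
the exact dual on the reversed graph with C. A system with no inputs is
reported uncontrollable.

### Finite-field rank oracle

As an independent cross-check, `generic_rank_oracle` substitutes random
nonzero weights drawn uniformly from GF(p), p = 2³¹ − 1, into the A and B
patterns, builds the Kalman block matrix `[B, AB, …, A^{N-1}B]` with exact
modular arithmetic and returns the maximum rank over 3 seeded draws. The
generic rank is an upper bound for every substitution and is attained unless
the draw hits a measure-zero set; with 3 draws over a 2³¹-size field the
failure probability is negligible at the tested sizes. Exact field
arithmetic avoids the floating-point instability of the N-th power Kalman
matrix. The oracle is for testing and is capped at N ≤ 64; production code
paths use the graph-theoretic tests, which are deterministic at any size.

## Maximum matching and minimal configurations

Driver nodes are the unmatched in-copies (sensor nodes the unmatched
out-copies) of a maximum matching of the out-copy/in-copy bipartite graph.
Maximum matchings are not unique; for reproducibility the implementation
uses Kuhn's augmenting-path algorithm processing out-copies in ascending
label order and trying successors in ascending label order. The matching
*size* (hence the driver count `max(N − |matching|, 1)`) is
tie-break-invariant and is verified against exhaustive search in tests.

When the matching is perfect the minimal sets are empty and any single node
grants controllability; the deterministic fallback is the smallest-label
node of the first source component (for sensors: sink component) in
condensation topological order, which also honours accessibility. An
isolated node is its own strongly connected component and is always both a
driver and a sensor.

## Input/output mapping

The base actuated set is the minimal driver set. A *critical source
component* is a source component of the SCC condensation containing no base
driver — exactly the components that violate accessibility. Each critical
component contributes one representative (its smallest label):
`path_finding` gives it a new dedicated input column, `signal_sharing` adds
it to input column 0. Both strategies therefore yield models passing both
structural tests, use the same actuated node set, and coincide exactly when
no critical source component exists; `signal_sharing` never uses more
input signals than `path_finding`.

## Measure conventions

Choices that admit more than one textbook definition are fixed as follows
(all asserted in the test suite):

* **density** = E / N², self-loops included in E;
* **diameter** = longest finite directed shortest path (hops);
* **percentSym** = 100 · (symmetric unordered pairs) / (connected unordered
  pairs); **percentLoops** = 100 · self-loops / E. Every edge set satisfies
  E = connected pairs + symmetric pairs + self-loops;
* **degree variance** = population variance (divide by N) of total degree;
* **Freeman centralization** of total degree, normalized by (N−1)(N−2);
* **Pearson α–β** (α, β ∈ {in, out}) = correlation over edges *u → v* of
  (α-degree of u, β-degree of v); out–in is classical assortativity. NaN
  when either margin is constant (undefined correlation);
* **closeness(i)** = |R(i)| / Σ_{j∈R(i)} d(i, j) over the set R(i) of nodes
  reachable from i (excluding i); 0 when nothing is reachable;
* **betweenness** (node and edge): directed, fractional shortest-path
  counting σ_st(·)/σ_st, endpoints excluded for nodes, unnormalized;
* **PageRank**: damping 0.85, uniform teleport, dangling mass redistributed
  uniformly, L1 tolerance 1e-12; reported as probabilities summing to 1 (the
  CLI tables print 4 decimals; multiply by 100 for percentages);
* **neighbor correlation(i)** = mean total degree of out-neighbours; 0 for
  out-degree 0;
* **control centrality(i)** = size of the forward-reachable set including i
  (a reachability count, which upper-bounds the single-input generic rank);
  observe centrality is the backward dual;
* **node relative degree** = raw hop distance from the nearest driver
  (drivers at 0); mean relative degree averages over all N nodes, so
  mean × N is always an integer; the **system relative degree** is the
  maximum over nodes and over the input (forward from drivers) and output
  (backward to sensors) sides;
* **driver/sensor classification**: `source` (in-degree 0); otherwise, if
  the node is reachable from another configured node it sits in a dilation —
  `external_dilation` when it is a leaf, `internal_dilation` otherwise;
  else `inaccessible`;
* **driver similarity(a, b)** = |{v : d(a,v) = d(b,v) < ∞}| / |{v : d(a,v) <
  ∞ or d(b,v) < ∞}|, diagonal 1;
* **endpoint similarity(u → v)** = mean of Jaccard(forward-reach(u),
  forward-reach(v)) and Jaccard(backward-reach(u), backward-reach(v)), reach
  sets including the node itself (1 on every edge of a cycle);
* **edge similarity(e, f)** = Jaccard of the ordered pairs (s, t) having at
  least one shortest path through e vs through f.

Reachability matrices: row i of R_c is the forward-reachable set of node i
with a true diagonal; R_o = R_cᵀ. These are reachability statements only —
reachability is necessary, not sufficient, for one node to control a set.

## Placement improvement

All methods place drivers using forward distances; sensors are handled by
running the identical algorithm on the reversed network. A placement is
*feasible* when every node is within the required relative degree r of the
placed set. Quality is the cost `α·r_achieved + (1−α)·mean relative degree`,
recomputed from the returned set (α ∈ [0, 1], default 0.5; r default 2 —
the case-study operating point).

* `setcov_grassroot`: greedy set cover over the distance-r balls
  {u : d(v, u) ≤ r}; maximal new coverage, ties to the smallest label. It
  ignores the minimal configuration, so the result meets the radius but
  structural controllability is *not* guaranteed.
* `setcov_retrofit`: the same greedy cover seeded with the minimal
  driver/sensor set, so the structural guarantee is preserved.
* `centmeas_retrofit`: retrofit loop adding, among nodes whose ball still
  covers something, the one with the highest closeness (ties to the smaller
  label). Not count-optimal by design.
* `mclasa`: k-medoid search with the minimal configuration as mandatory
  medoids. For each k (incremented until feasibility, k = N always feasible)
  simulated annealing proposes single swaps of a free medoid with a
  non-medoid and accepts by the Metropolis rule on the placement cost, with
  unreachable assignment distances penalised at N hops. Defaults: initial
  temperature 1.0, geometric cooling 0.95, 500 iterations per k — desk-scale,
  reproducible runs; all exposed in `ImprovementConfig`.
* `gdfcmsa`: the same search with the assignment term fuzzified by c-medoid
  memberships u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)}, fuzzifier m = 2, nodes at
  distance 0 assigned crisply; the annealing objective is
  α·r_achieved + (1−α)·(Σ u_ij² d_ij)/N.

The annealing methods are stochastic heuristics: only feasibility, the
superset-of-minimal guarantee and exact cost accounting are contractual;
the particular medoids depend on the seed (fixed seed ⇒ identical result).

## Robustness

Leave-one-out analysis deletes one node and its incident edges, drops it
from every input column and output row (emptied columns/rows are dropped,
not reassigned — damaged-system semantics, no silent repair), and re-runs
the graph-theoretic structural tests on the (N−1)-state system. Reported:
per-scenario verdicts, robust counts, fractions (count/N, 4 decimals) and
the critical node sets (complement of the robust scenarios). The
graph-theoretic test, not the numeric oracle, is used here so the report is
deterministic at any network size.

## Synthetic generators and what tests show

The `fixtures` module generates chains, cycles, stars, Erdős–Rényi digraphs,
mutually coupled node pairs (`reciprocal_pairs`, guaranteeing a perfect
matching by construction — the regime of reciprocally connected command
interneurons) and `scc_mosaic` (cycles wired into a prescribed condensation
DAG, the regime where the two mapping strategies diverge). Generators are
deterministic under their seed.

These fixtures exercise every structural regime the algorithms branch on
(unmatched nodes, perfect matching, dilations, inaccessible components,
multiple source SCCs), but they are not connectome-realistic: real neuronal
networks have heavy-tailed degrees, reciprocity far above the Erdős–Rényi
expectation and modular structure. Passing tests therefore certify the
*algorithms and definitions*, not any biological claim about a particular
network. Test problem sizes: exhaustive matching oracles at N ≤ 8,
rank-oracle agreement on 200 digraphs at N ≤ 10, path-enumeration oracles
at N = 15 — sizes where exhaustive verification is exact and fast.

## Degenerate inputs and numerical notes

Empty networks are rejected; unreachable distances are reported distinctly
(`None` in the API, `inf` in distance matrices, the string `"inf"` in JSON);
Pearson correlations on constant margins are NaN rather than 0; closeness
and neighbor correlation of sinks are 0. CSV tables round to 4 decimals for
readability; JSON reports keep full precision and record the seed.

## Known limitations

Linear(ised) dynamics only; no minimum-energy (Gramian) analysis; no
multi-node or edge-removal attack models; the annealing methods make no
optimality claim; per-node values on large real networks depend on the
conventions above and may differ from other toolboxes that chose
differently.
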