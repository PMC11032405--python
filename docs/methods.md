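# Methods

## Model and procedure

The package solves the maximum weight clique problem exactly on finite
undirected graphs with positive integer vertex weights. The search is a
depth-first branch and bound. State at a node: the growing clique Q (with
running weight), the incumbent Qmax, and an ordered candidate sequence R
of vertices adjacent to all of Q, each carrying an upper bound (wcolor)
on the weight of any clique through it within R.

Bounds come from greedy coloring. R is consumed in its incoming order;
each vertex joins the lowest-numbered color class containing none of its
neighbors, opening a new class when needed. A class's weight is the
maximum vertex weight in it. Since a clique takes at most one vertex per
class, a clique whose largest class index is k weighs at most the prefix
sum ub_k of class weights 1..k; ub_k is the wcolor of every vertex in
class k. The prefix interpretation (classes 1..k, not the k lightest
classes) is essential: it is what makes the prune sound, and it
reproduces the hand-traceable bounds of the 7-vertex example (21, 20, 15,
7).

Pruning: `min_k_w` is the smallest class index whose prefix sum exceeds
the gap weight(Qmax) − weight(Q) (maxno + 1 when none does). Vertices in
classes below `min_k_w` are emitted first, in incoming relative order,
with wcolor 0; classes `min_k_w`..maxno follow in class order, vertices
in insertion order. The expansion loop pops candidates from the back and
stops the whole level at the first vertex failing
weight(Q) + wcolor(p) > weight(Qmax): wcolors are nondecreasing along the
order, so every remaining candidate fails too.

The precise prune guarantee is worth stating carefully: a selected vertex
is only ever extended with candidates *earlier* in the order, so pruning
a vertex discards exactly the cliques lying wholly inside the pruned
region, and any such clique is bounded by ub_{min_k_w − 1} ≤ gap by
minimality of `min_k_w`. A blanket claim over *all* cliques containing a
pruned vertex would be false (such a clique may include a high-color
vertex and exceed the gap); those cliques are explored from the
high-color vertex's own selection, so exactness is unaffected. The test
suite checks the region-restricted form by exhaustive enumeration.

### Bound test: wcolor, not vertex weight

One could instead test weight(Q) + W(p) > weight(Qmax) before adding p.
That inequality is not an admissible prune: a vertex light by itself may
still lead to a heavy clique, so rejecting on it (and, with the
stop-the-level rule, everything before it) can discard the optimum. The
wcolor form is the one consistent with a correct bound and with the
worked example's four recorded decisions, and is what this package
implements.

### Dynamic variant

The static variant degree-sorts vertices once. The dynamic variant
additionally recomputes, before coloring a candidate set Rp, each
candidate's degree within the induced subgraph G(Rp) and stable-sorts Rp
by decreasing induced degree — but only while T[level] < tlimit, where
T[level] is the fraction of all expansion steps so far that were taken at
depths 1..level. One step = one vertex selection in the expansion loop,
counted at the level of the selection; T is evaluated just before
coloring, and treated as 0 before any step has completed. The recount
costs O(|Rp|²), so the gate confines it to shallow levels where Rp is
large and tighter bounds save the most work. `tlimit` defaults to 0.025;
at 0 the gate never opens and the run is step-for-step identical to the
static variant (asserted in tests, counters included). Both variants
return the same optimal weight always — the gate shapes the tree, never
the result.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `tlimit` | 0.025 | step-fraction gate for dynamic reordering, in [0, 1]; speed-only |
| `mu`, `sigma` | 1,000,000 / 200,000 | mean and SD of the rounded-normal weight distribution of the generator |
| `p` | — | independent edge probability of the G(n, p) generator |
| `w2` | 3 | weight of vertex 2 in the 7-vertex example (1..7 leave its trace unchanged) |
| oracle `limit` | 30 (recursion) / 20 (subset scan) | refusal guards on brute force |

Weights are exact Python integers throughout; no overflow at any
realistic scale (10⁴ vertices at weights near 2×10⁶ stays far below
machine-relevant bounds since arithmetic is arbitrary-precision).

## Synthetic data

`random_weighted_graph` draws each unordered pair independently with
probability p (pairs visited in fixed i < j lexicographic order on a
single RNG stream, so a seed fully determines the instance) and assigns
weights as N(mu, sigma) rounded half-away-from-zero to the nearest
integer, redrawing any draw that rounds below 1. Rejection rather than
clamping preserves the distribution shape; at the default scale a
nonpositive draw is a ≈5σ event, so the choice is immaterial there but
keeps small-mu configurations well-defined. `shuffle_vertices` applies a
uniform random permutation to the labels, preserving structure.

What the generator does *not* emulate: the degree correlations, weight
clustering, and block structure of real correspondence graphs from
molecular matching. Passing the random-suite tests certifies exactness
and order-invariance of the solver on Erdős–Rényi-type instances; claims
about wall-clock performance on structured chemical graphs do not follow
from them.

The 7-vertex `example_graph` is reconstructed from its published
step-by-step narration. The weight of vertex 2 is not pinned down by any
printed number; it is exposed as `w2` (default 3) and every traced
quantity is invariant for w2 in 1..7. The narration's degree summary is
internally inconsistent (an odd degree sum); vertex 2 having degree 3 is
the unique resolution consistent with every printed value, and is what
the fixture encodes.

## Numerical and design choices

* **Tie-breaks.** All sorts are stable: equal-degree vertices keep their
  incoming relative order. The solver contains no randomness; a fixed
  input labeling gives a bit-identical run.
* **Candidate inheritance.** Rp preserves the relative order of the
  parent sequence; the greedy coloring consumes it as received. Bound
  tightness depends on this inherited (degree-derived) order.
* **Degenerate inputs.** n = 0 is a solver error; a single vertex returns
  itself; edgeless graphs return the heaviest vertex. Empty candidate
  sets never reach the coloring routine (the expansion checks first).
* **Recursion.** Depth is bounded by the clique number; the recursion
  limit is raised to n + 1000 before searching.
* **Worked-example branch order.** The published narration explores the
  Q = {3} level in the order vertex 1 then vertex 5; any copy-back rule
  consistent with the narration's own root order visits 5 first. This
  package follows the pseudocode semantics (5 first), which reaches the
  optimum one branch earlier and then bound-kills the vertex-1 branch;
  every printed bound and weight is still reproduced, the Step-8 branch
  numbers by direct evaluation at that state.
* **DIMACS dialect.** Weights ride in `v i w` lines in the instance file
  itself (the convention of weighted-clique benchmark distributions);
  absent lines default to 1, `p col` is accepted for `p edge`, duplicate
  edge lines are merged, self-loops are errors. Internally vertices are
  0-based; all I/O and CLI output is 1-based.
* **Benchmarking.** Each repeat solves a freshly relabeled copy (shuffle
  seed derived deterministically from the run seed, graph index and
  repeat index). Sample SD (ddof = 1), reported as 0 for a single repeat.
  Speedup of A over reference B is meanTime(B)/meanTime(A). Timing values
  are reported, never asserted — they are hardware facts, not method
  facts. An optional reporting cap can clip per-run times for parity with
  capped published tables; nothing depends on it.

## Problem sizes in the shipped checks

The exactness suite runs both variants against brute-force enumeration on
256 random instances (n = 10..25, p ∈ {0.2, 0.5, 0.8, 0.9}, default
weight scale); order-invariance uses 100 relabelings of an n = 60,
p = 0.7 instance; coloring soundness enumerates all cliques of n ≤ 15
graphs. These sizes keep the naive references honest (the oracles are
deliberately unoptimized) while exercising every branch of the solver;
the solver itself handles far larger instances.

## Known limitations

* Pure-Python core: exactness-first, not a speed record; large dense
  instances (hundreds of vertices at high density) are better served by
  compiled solvers.
* No anytime/heuristic mode: the solver proves optimality or runs on.
* Vertex weights only — no edge weights, real weights, directed graphs or
  multigraphs.
* The dynamic gate's step-accounting is one documented reading of a
  heuristic specified only loosely in the literature it derives from; it
  affects speed, never results (the result contract is tested
  independently of the gate).
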