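# mwclique

Exact **maximum weight clique** (MWC) search on vertex-weighted undirected
graphs, by branch and bound with a weighted greedy-coloring upper bound.

Given a graph G = (V, E) with a positive integer weight W(v) on every
vertex, the MWC problem asks for a clique Q ⊆ V maximizing
weight(Q) = Σ_{v∈Q} W(v). The problem is NP-hard and shows up throughout
cheminformatics and drug discovery: the vertices of a correspondence
(modular product) graph of two molecules are compatible feature pairs, and
its heaviest cliques encode maximum common substructures. This package is
for anyone who needs provably optimal weighted cliques on such graphs, a
reproducible random-instance generator, and a harness for comparing
solver variants.

## The algorithm

The solver grows a clique Q depth-first while maintaining the incumbent
Qmax, the heaviest clique found so far. At every search node the candidate
set R (vertices adjacent to all of Q) is greedily partitioned into
independent color classes C[1..maxno], each class carrying the maximum
weight of its vertices. Because a clique can use at most one vertex per
class, any clique K ⊆ R whose largest class index is k satisfies

    weight(K) ≤ Σ_{n=1..k} weight(C[n])  =: ub_k.

Each candidate is tagged with the prefix sum of its class, its *wcolor*.
The class index `min_k_w` — the smallest k with ub_k exceeding the gap
weight(Qmax) − weight(Q) — splits R: vertices in lower classes cannot
yield an improvement and are moved to the front with wcolor 0, the rest
follow in class order. The expansion loop consumes R from the back
(largest bounds first) and, on the first vertex p failing
weight(Q) + wcolor(p) > weight(Qmax), abandons the whole level, since
wcolors are nondecreasing along the order.

Two variants share this machinery:

* **static** — vertices are sorted by decreasing degree once, at the root;
* **dynamic** — at levels where the fraction of expansion steps spent at
  depths up to the current level is below `tlimit` (default 0.025),
  candidates are re-sorted by their degree inside the subgraph they
  induce before coloring. The O(|Rp|²) recount is thereby confined to the
  shallow levels where candidate sets are large and tighter bounds pay.

Both return the exact optimum; they differ only in the explored tree.

## Worked example

The library ships the 7-vertex illustration graph whose search can be
traced by hand (weights 2, 3, 5, 7, 8, 2, 1 on vertices 1–7):

```python
from mwclique import example_graph, max_clique_weight, write_dimacs

G = example_graph()
result = max_clique_weight(G)
print(result.weight)                          # 20
print(sorted(v + 1 for v in result.clique))   # [3, 4, 5]
print(result.incumbent_history)               # (18, 20)
open("example.clq", "w").write(write_dimacs(G))
```

The search first stores the clique {4, 5, 6, 7} of weight 18, then prunes
its way to the optimum {3, 4, 5} of weight 20. The same run from the
shell:

```
$ mwclique solve example.clq
weight: 20
clique: 3 4 5
steps: 13
incumbents: 18 20
```

`steps` counts expansion-loop iterations; `incumbents` is the sequence of
incumbent weights, strictly increasing by construction. Other subcommands:
`mwclique gen --n 200 --p 0.9 --seed 1 -o g.clq` writes a random DIMACS
instance with rounded-normal weights (mean 1,000,000, SD 200,000 by
default), `mwclique oracle g.clq` runs the guarded brute-force reference,
and `mwclique bench --config cfg.json -o out.csv` runs the
shuffle-and-repeat benchmark protocol (each repeat solves a freshly
relabeled copy; mean ± sample SD of wall times, optimum, and an
all-runs-agree flag per instance and algorithm).

Graph files use the ASCII DIMACS clique format (`p edge n m`, `e i j`)
extended with `v i w` vertex-weight lines; files without `v` lines are
valid and default every weight to 1.

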