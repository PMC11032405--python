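"""Vertex-weighted undirected graph model.

Vertices are identified by contiguous 0-based integers. Weights are
positive integers; adjacency is symmetric and loop-free. This is the
in-memory representation used by the coloring bound and the
branch-and-bound search; DIMACS 1-based ids are converted at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence


class GraphStructureError(ValueError):
    """Structurally invalid graph input (self-loop, bad endpoint, ...)."""


class WeightDomainError(ValueError):
    """Vertex weight outside the positive-integer domain."""


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph with a positive integer weight per vertex.

    Attributes
    ----------
    n : int
        Number of vertices, identified ``0 .. n-1``.
    adjacency : tuple of frozenset
        ``adjacency[v]`` is the neighbor set of ``v``.
    weights : tuple of int
        ``weights[v] >= 1`` for every vertex.
    """

    n: int
    adjacency: tuple[frozenset[int], ...]
    weights: tuple[int, ...]

    @property
    def max_degree(self) -> int:
        """Largest vertex degree; 0 for edgeless (or empty) graphs."""
        return max((len(a) for a in self.adjacency), default=0)

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    @property
    def num_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield each edge once as an ordered pair ``(i, j)`` with ``i < j``."""
        for i in range(self.n):
            for j in sorted(self.adjacency[i]):
                if i < j:
                    yield (i, j)

    @cached_property
    def adjacency_bits(self) -> tuple[int, ...]:
        """Neighbor sets as integer bitmasks (bit v set iff v is a neighbor).

        Used in the hot loops of coloring and search, where an AND against
        a class/candidate mask replaces per-vertex set membership tests.
        """
        return tuple(
            sum(1 << u for u in neigh) for neigh in self.adjacency
        )

    def is_clique(self, vertices: Iterable[int]) -> bool:
        vs = list(vertices)
        return all(
            vs[j] in self.adjacency[vs[i]]
            for i in range(len(vs))
            for j in range(i + 1, len(vs))
        )

    def clique_weight(self, vertices: Iterable[int]) -> int:
        return sum(self.weights[v] for v in vertices)


def build_graph(
    n: int,
    edges: Iterable[tuple[int, int]],
    weights: Sequence[int],
) -> WeightedGraph:
    """Construct a :class:`WeightedGraph`, validating all invariants.

    Duplicate edges (in either orientation) are silently deduplicated;
    self-loops are rejected because clique semantics are undefined on them.

    Raises
    ------
    GraphStructureError
        On a self-loop or an endpoint outside ``0 .. n-1``.
    WeightDomainError
        On a non-integral or nonpositive weight, or wrong weight count.
    """
    if n < 0:
        raise GraphStructureError(f"vertex count must be nonnegative, got {n}")
    if len(weights) != n:
        raise WeightDomainError(
            f"expected {n} weights, got {len(weights)}"
        )
    wts = []
    for v, w in enumerate(weights):
        if isinstance(w, bool) or int(w) != w:
            raise WeightDomainError(f"weight of vertex {v} is not an integer: {w!r}")
        if w < 1:
            raise WeightDomainError(f"weight of vertex {v} must be >= 1, got {w}")
        wts.append(int(w))
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges:
        if i == j:
            raise GraphStructureError(f"self-loop on vertex {i}")
        if not (0 <= i < n and 0 <= j < n):
            raise GraphStructureError(f"edge ({i}, {j}) has an endpoint outside 0..{n - 1}")
        adj[i].add(j)
        adj[j].add(i)
    return WeightedGraph(
        n=n,
        adjacency=tuple(frozenset(a) for a in adj),
        weights=tuple(wts),
    )


def validate(G: WeightedGraph) -> None:
    """Assert the structural invariants of a graph; raise if violated."""
    if len(G.adjacency) != G.n or len(G.weights) != G.n:
        raise GraphStructureError("field lengths disagree with vertex count")
    for v in range(G.n):
        if v in G.adjacency[v]:
            raise GraphStructureError(f"self-loop on vertex {v}")
        for u in G.adjacency[v]:
            if not (0 <= u < G.n):
                raise GraphStructureError(f"neighbor {u} of {v} out of range")
            if v not in G.adjacency[u]:
                raise GraphStructureError(f"asymmetric adjacency between {u} and {v}")
        if G.weights[v] < 1 or int(G.weights[v]) != G.weights[v]:
            raise WeightDomainError(f"invalid weight on vertex {v}")


def sort_by_decreasing_degree(
    G: WeightedGraph, vertices: Iterable[int]
) -> list[int]:
    """Sort vertices by decreasing degree in ``G``, stably.

    Ties keep the relative order of the input sequence, which makes the
    whole search deterministic for a fixed input labeling.
    """
    vs = list(vertices)
    for v in vs:
        if not (0 <= v < G.n):
            raise IndexError(f"vertex {v} not in graph")
    return sorted(vs, key=lambda v: -len(G.adjacency[v]))


def induced_subgraph(G: WeightedGraph, S: Iterable[int]) -> WeightedGraph:
    """Subgraph induced by vertex set ``S``, relabeled ``0..|S|-1``.

    Vertices of ``S`` are taken in sorted order; weights are restricted
    accordingly.
    """
    keep = sorted(set(S))
    for v in keep:
        if not (0 <= v < G.n):
            raise IndexError(f"vertex {v} not in graph")
    new_id = {v: i for i, v in enumerate(keep)}
    adj = tuple(
        frozenset(new_id[u] for u in G.adjacency[v] if u in new_id)
        for v in keep
    )
    return WeightedGraph(
        n=len(keep),
        adjacency=adj,
        weights=tuple(G.weights[v] for v in keep),
    )


def relabel(G: WeightedGraph, perm: Sequence[int]) -> WeightedGraph:
    """Apply a vertex permutation: vertex ``v`` becomes ``perm[v]``.

    The result is isomorphic to ``G`` — edge count, degree multiset and
    weight multiset are preserved; only the labeling changes.
    """
    if sorted(perm) != list(range(G.n)):
        raise ValueError("perm is not a bijection on 0..n-1")
    adj: list[frozenset[int]] = [frozenset()] * G.n
    wts: list[int] = [0] * G.n
    for v in range(G.n):
        adj[perm[v]] = frozenset(perm[u] for u in G.adjacency[v])
        wts[perm[v]] = G.weights[v]
    return WeightedGraph(n=G.n, adjacency=tuple(adj), weights=tuple(wts))


def inverse_permutation(perm: Sequence[int]) -> list[int]:
    inv = [0] * len(perm)
    for v, t in enumerate(perm):
        inv[t] = v
    return inv
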