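"""Exact maximum weight clique search by branch and bound.

Two entry points share one recursion:

* :func:`max_clique_weight` — vertices are degree-sorted once at the root;
  every search node greedily colors its candidate set to obtain per-vertex
  weight bounds (wcolors) used for pruning.
* :func:`max_clique_dyn_weight` — additionally, at search levels where the
  fraction of expansion steps spent at depths up to the current level is
  below ``tlimit``, candidate vertices are re-sorted by their degree in
  the subgraph they induce before coloring. Recomputing induced degrees
  costs O(|Rp|^2), so the gate restricts it to the shallow levels where
  candidate sets are large and tighter bounds pay off.

Both variants return the same optimal weight; they differ only in the
shape (and size) of the explored search tree.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Callable, Optional

from .coloring import color_sort_weight
from .graph import WeightedGraph, sort_by_decreasing_degree

logger = logging.getLogger(__name__)

DEFAULT_TLIMIT = 0.025

# Called at each vertex addition with (level, vertex, weight of the grown clique).
Observer = Callable[[int, int, int], None]


@dataclass
class SearchState:
    """Mutable state of one branch-and-bound run."""

    Q: list[int] = field(default_factory=list)
    weight_Q: int = 0
    Qmax: tuple[int, ...] = ()
    weight_Qmax: int = 0
    steps_at_level: list[int] = field(default_factory=list)
    steps_total: int = 0
    incumbent_history: list[int] = field(default_factory=list)

    def record_step(self, level: int) -> None:
        while len(self.steps_at_level) < level:
            self.steps_at_level.append(0)
        self.steps_at_level[level - 1] += 1
        self.steps_total += 1

    def step_fraction(self, level: int) -> float:
        """Fraction of all steps so far spent at depths 1..level (0 if none)."""
        if self.steps_total == 0:
            return 0.0
        return sum(self.steps_at_level[:level]) / self.steps_total


@dataclass(frozen=True)
class CliqueResult:
    """Outcome of a clique search.

    ``incumbent_history`` lists the incumbent weight at every update, in
    order; it is strictly increasing and ends at ``weight``.
    """

    clique: tuple[int, ...]
    weight: int
    steps_total: int
    incumbent_history: tuple[int, ...]
    variant: str
    tlimit: Optional[float] = None


class _Search:
    def __init__(
        self,
        G: WeightedGraph,
        dynamic: bool,
        tlimit: float,
        observer: Optional[Observer] = None,
    ):
        self.G = G
        self.dynamic = dynamic
        self.tlimit = tlimit
        self.observer = observer
        self.state = SearchState()

    def run(self) -> SearchState:
        G = self.G
        if G.n == 0:
            raise ValueError("cannot search an empty graph")
        # recursion depth is bounded by the clique number (<= n)
        sys.setrecursionlimit(max(sys.getrecursionlimit(), G.n + 1000))
        R = sort_by_decreasing_degree(G, range(G.n))
        cs = color_sort_weight(G, R, 0, 0)
        self._expand(cs.order, cs.wcolors, 1)
        return self.state

    def _expand(self, order: list[int], wcolors: list[int], level: int) -> None:
        G = self.G
        st = self.state
        while order:
            p = order.pop()
            wc = wcolors.pop()
            st.record_step(level)
            if st.weight_Q + wc <= st.weight_Qmax:
                # wcolors are nondecreasing along the order, so every
                # remaining candidate fails the bound as well
                break
            st.Q.append(p)
            st.weight_Q += G.weights[p]
            if self.observer is not None:
                self.observer(level, p, st.weight_Q)
            ap = G.adjacency[p]
            Rp = [v for v in order if v in ap]
            if Rp:
                if self.dynamic and st.step_fraction(level) < self.tlimit:
                    Rp = self._resort_by_induced_degree(Rp)
                cs = color_sort_weight(G, Rp, st.weight_Q, st.weight_Qmax)
                self._expand(cs.order, cs.wcolors, level + 1)
            elif st.weight_Q > st.weight_Qmax:
                st.Qmax = tuple(st.Q)
                st.weight_Qmax = st.weight_Q
                st.incumbent_history.append(st.weight_Q)
                logger.debug(
                    "incumbent update: weight=%d clique=%s", st.weight_Q, st.Qmax
                )
            st.Q.pop()
            st.weight_Q -= G.weights[p]

    def _resort_by_induced_degree(self, Rp: list[int]) -> list[int]:
        """Stable-sort candidates by decreasing degree within G(Rp)."""
        bits = self.G.adjacency_bits
        mask = 0
        for v in Rp:
            mask |= 1 << v
        deg = {v: (bits[v] & mask).bit_count() for v in Rp}
        return sorted(Rp, key=lambda v: -deg[v])


def _run(
    G: WeightedGraph,
    dynamic: bool,
    tlimit: float,
    variant: str,
    observer: Optional[Observer] = None,
) -> CliqueResult:
    st = _Search(G, dynamic=dynamic, tlimit=tlimit, observer=observer).run()
    return CliqueResult(
        clique=st.Qmax,
        weight=st.weight_Qmax,
        steps_total=st.steps_total,
        incumbent_history=tuple(st.incumbent_history),
        variant=variant,
        tlimit=tlimit if dynamic else None,
    )


def max_clique_weight(
    G: WeightedGraph, observer: Optional[Observer] = None
) -> CliqueResult:
    """Find a maximum weight clique (static vertex order).

    Vertices are sorted by decreasing degree once; the returned clique's
    weight is the exact optimum. Deterministic for a fixed input labeling.
    """
    return _run(G, dynamic=False, tlimit=0.0, variant="static", observer=observer)


def max_clique_dyn_weight(
    G: WeightedGraph,
    tlimit: float = DEFAULT_TLIMIT,
    observer: Optional[Observer] = None,
) -> CliqueResult:
    """Find a maximum weight clique with dynamically recomputed ordering.

    While the step fraction at a level stays below ``tlimit`` (default
    0.025), candidate sets are re-sorted by their induced-subgraph degree
    before coloring, which tightens the bounds near the root. With
    ``tlimit=0`` the gate never opens and the run is step-for-step
    identical to :func:`max_clique_weight`.
    """
    if not 0.0 <= tlimit <= 1.0:
        raise ValueError(f"tlimit must lie in [0, 1], got {tlimit}")
    return _run(G, dynamic=True, tlimit=tlimit, variant="dynamic", observer=observer)


def solve(
    G: WeightedGraph,
    variant: str = "static",
    tlimit: float = DEFAULT_TLIMIT,
    observer: Optional[Observer] = None,
) -> CliqueResult:
    """Dispatch to the static or dynamic search variant by name."""
    if variant == "static":
        return max_clique_weight(G, observer=observer)
    if variant == "dynamic":
        return max_clique_dyn_weight(G, tlimit=tlimit, observer=observer)
    raise ValueError(f"unknown variant {variant!r}; expected 'static' or 'dynamic'")
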