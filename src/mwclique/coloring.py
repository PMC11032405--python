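"""Weighted greedy coloring bound for the clique search.

The candidate set at every search node is partitioned into independent
color classes by a single greedy pass. Since a clique can contain at most
one vertex per independent class, the weight of any clique inside the
candidate set whose largest class index is k is bounded by the sum of the
per-class maximum weights of classes 1..k. That prefix sum, attached to
each candidate vertex as its *wcolor*, is the pruning bound the
branch-and-bound search tests before extending the growing clique.

Vertices whose bound cannot close the gap to the incumbent are moved to
the front of the candidate order with wcolor 0, so the search loop — which
consumes candidates from the back — can stop at the first failing vertex.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import accumulate
from typing import Sequence

from .graph import WeightedGraph


@dataclass
class ColorPartition:
    """Greedy color classes of a candidate set.

    ``classes[k]`` (0-based here; class number k+1) is an independent set
    listed in insertion order; ``class_weights[k]`` is the maximum vertex
    weight within it.
    """

    classes: list[list[int]]
    class_weights: list[int]

    @property
    def maxno(self) -> int:
        """Number of color classes used."""
        return len(self.classes)


@dataclass
class BoundedCandidateSet:
    """A reordered candidate sequence with per-position weight bounds.

    ``order`` and ``wcolors`` are parallel: ``wcolors[i]`` bounds the
    weight of any clique through ``order[i]`` within the candidate set.
    The sequence is nondecreasing in wcolor, with all pruned vertices
    (classes below ``min_k_w``, wcolor 0) at the front.
    """

    order: list[int]
    wcolors: list[int]
    color_of: dict[int, int]
    min_k_w: int
    partition: ColorPartition
    prefix_weights: list[int]

    def wcolor(self, v: int) -> int:
        """Bound attached to vertex ``v`` (0 if pruned)."""
        return self.wcolors[self.order.index(v)]


def color_sort_weight(
    G: WeightedGraph,
    R: Sequence[int],
    weight_Q: int,
    weight_Qmax: int,
) -> BoundedCandidateSet:
    """Greedily color candidate set ``R`` and assign clique-weight bounds.

    Parameters
    ----------
    G : WeightedGraph
        The full graph (adjacency and weights).
    R : sequence of int
        Nonempty candidate vertex sequence. The greedy pass consumes it in
        the given order; bound tightness depends on the caller passing a
        decreasing-degree order.
    weight_Q : int
        Weight of the clique grown so far.
    weight_Qmax : int
        Weight of the incumbent (best clique found so far).

    Returns
    -------
    BoundedCandidateSet
        Candidates reordered as [pruned vertices in incoming relative
        order, wcolor 0] followed by classes ``min_k_w .. maxno`` in class
        order (within-class insertion order), each vertex carrying the
        prefix-sum bound of its class.

    Notes
    -----
    ``min_k_w`` is the smallest class index whose prefix sum of class
    weights exceeds ``weight_Qmax - weight_Q``; vertices in lower classes
    cannot produce a clique heavier than the incumbent and are pruned
    (``maxno + 1`` when no class qualifies, i.e. the whole set prunes).
    """
    if not R:
        raise ValueError("candidate set must be nonempty")
    adj_bits = G.adjacency_bits
    weights = G.weights

    class_masks: list[int] = []
    classes: list[list[int]] = []
    class_weights: list[int] = []
    color_of: dict[int, int] = {}

    for p in R:
        ap = adj_bits[p]
        for k in range(len(class_masks)):
            if ap & class_masks[k] == 0:
                break
        else:
            k = len(class_masks)
            class_masks.append(0)
            classes.append([])
            class_weights.append(0)
        class_masks[k] |= 1 << p
        classes[k].append(p)
        if weights[p] > class_weights[k]:
            class_weights[k] = weights[p]
        color_of[p] = k + 1

    prefix = list(accumulate(class_weights))
    maxno = len(classes)
    gap = weight_Qmax - weight_Q
    min_k_w = maxno + 1
    for k in range(maxno):
        if prefix[k] > gap:
            min_k_w = k + 1
            break

    order: list[int] = []
    wcolors: list[int] = []
    if min_k_w > 1:
        for p in R:  # pruned region keeps the incoming relative order
            if color_of[p] < min_k_w:
                order.append(p)
                wcolors.append(0)
    for k in range(min_k_w - 1, maxno):
        ub_k = prefix[k]
        for p in classes[k]:
            order.append(p)
            wcolors.append(ub_k)

    return BoundedCandidateSet(
        order=order,
        wcolors=wcolors,
        color_of=color_of,
        min_k_w=min_k_w,
        partition=ColorPartition(classes=classes, class_weights=class_weights),
        prefix_weights=prefix,
    )
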