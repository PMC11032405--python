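"""Naive brute-force references for maximum weight clique.

Two deliberately unoptimized strategies — a plain clique-extension
recursion and an exhaustive subset scan — used to certify the
branch-and-bound solver on small graphs. No coloring, no weight bounds:
exact by construction, exponential by design.
"""

from __future__ import annotations

from .graph import WeightedGraph
from .search import CliqueResult

DEFAULT_VERTEX_LIMIT = 30
SUBSET_SCAN_LIMIT = 20


class OracleLimitError(ValueError):
    """Graph too large for deliberate brute-force enumeration."""


def brute_force_mwc(G: WeightedGraph, limit: int = DEFAULT_VERTEX_LIMIT) -> CliqueResult:
    """Enumerate every clique by plain recursion; return the heaviest.

    Candidates are restricted to higher-numbered neighbors so each clique
    is visited exactly once. ``steps_total`` counts enumerated cliques.
    """
    if G.n > limit:
        raise OracleLimitError(
            f"brute force refused on n={G.n} > limit={limit}"
        )
    bits = G.adjacency_bits
    weights = G.weights
    best_w = 0
    best: tuple[int, ...] = ()
    history: list[int] = []
    count = 0

    def rec(clique: list[int], weight: int, cand: int) -> None:
        nonlocal best_w, best, count
        count += 1
        if weight > best_w:
            best_w = weight
            best = tuple(clique)
            history.append(weight)
        while cand:
            v = (cand & -cand).bit_length() - 1
            cand &= cand - 1
            clique.append(v)
            rec(clique, weight + weights[v], cand & bits[v])
            clique.pop()

    all_higher = (1 << G.n) - 1
    rec([], 0, all_higher)
    return CliqueResult(
        clique=best,
        weight=best_w,
        steps_total=count,
        incumbent_history=tuple(history),
        variant="brute-force",
    )


def subset_scan_mwc(G: WeightedGraph, limit: int = SUBSET_SCAN_LIMIT) -> CliqueResult:
    """Second, independent reference: test all 2^n vertex subsets.

    Exists so the primary oracle is itself cross-validated; practical only
    for very small n.
    """
    if G.n > limit:
        raise OracleLimitError(
            f"subset scan refused on n={G.n} > limit={limit}"
        )
    bits = G.adjacency_bits
    weights = G.weights
    best_w = 0
    best: tuple[int, ...] = ()
    history: list[int] = []
    for mask in range(1 << G.n):
        members = [v for v in range(G.n) if mask >> v & 1]
        if any(
            members[j] not in G.adjacency[members[i]]
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ):
            continue
        w = sum(weights[v] for v in members)
        if w > best_w:
            best_w = w
            best = tuple(members)
            history.append(w)
    return CliqueResult(
        clique=best,
        weight=best_w,
        steps_total=1 << G.n,
        incumbent_history=tuple(history),
        variant="subset-scan",
    )
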