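"""Random vertex-weighted graph generation and the worked 7-vertex example.

Edges follow the G(n, p) model: every unordered vertex pair is connected
independently with probability p. Weights are independent normal draws
(defaults mu = 1,000,000, sigma = 200,000) rounded to the nearest integer;
draws that round below 1 are rejected and redrawn, which at the default
scale is an ~5.7-sigma event and therefore essentially never happens, but
keeps small-mu configurations valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graph import WeightedGraph, build_graph, relabel


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the random weighted graph model."""

    n: int
    p: float
    mu: float = 1_000_000.0
    sigma: float = 200_000.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"edge probability must lie in [0, 1], got {self.p}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


def draw_weights(
    n: int,
    mu: float = 1_000_000.0,
    sigma: float = 200_000.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[int]:
    """Draw ``n`` positive integer weights from a rounded normal.

    Each draw is N(mu, sigma) rounded half-away-from-zero to the nearest
    integer; any draw rounding below 1 is rejected and redrawn, so the
    result is always a positive integer.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    while pending.size:
        x = rng.normal(mu, sigma, size=pending.size)
        w = np.floor(x + 0.5).astype(np.int64)
        ok = w >= 1
        out[pending[ok]] = w[ok]
        pending = pending[~ok]
    return [int(w) for w in out]


def random_weighted_graph(params: GeneratorParams) -> WeightedGraph:
    """Generate a G(n, p) graph with rounded-normal vertex weights.

    Pairs are visited in fixed lexicographic order (i < j) and edge draws
    precede weight draws on a single RNG stream, so a seed fully
    determines the graph.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    ii, jj = np.triu_indices(n, k=1)
    u = rng.random(ii.size)
    keep = u < params.p
    edges = list(zip(ii[keep].tolist(), jj[keep].tolist()))
    weights = draw_weights(n, params.mu, params.sigma, rng=rng)
    return build_graph(n, edges, weights)


def shuffle_vertices(G: WeightedGraph, seed: Optional[int] = None) -> WeightedGraph:
    """Relabel vertices by a uniformly random permutation.

    The structure (edge set up to relabeling, degree and weight multisets)
    is preserved; only vertex numbers move. Used to probe the solver's
    sensitivity to input order.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(G.n).tolist()
    return relabel(G, perm)


#: 1-based edge list of the 7-vertex illustration graph.
_EXAMPLE_EDGES_1BASED = [
    (4, 5), (4, 6), (4, 7), (5, 6), (5, 7), (6, 7),
    (1, 6), (1, 3), (1, 2), (1, 4), (2, 3), (2, 7), (3, 4), (3, 5),
]


def example_graph(w2: int = 3) -> WeightedGraph:
    """The 7-vertex weighted graph used to illustrate the search.

    Vertices are numbered 1..7 externally (internal ids 0..6, so external
    vertex k is internal ``k - 1``). Weights are
    ``{1: 2, 2: w2, 3: 5, 4: 7, 5: 8, 6: 2, 7: 1}``; vertex 4 has degree 5
    and all maximum-weight-clique structure lives on {3, 4, 5} (weight 20),
    with {4, 5, 6, 7} (weight 18) found first by the search.

    ``w2`` — the weight of vertex 2, which never enters any incumbent —
    may be any integer in 1..7; larger values would change the coloring
    bounds on the branches that the illustration prunes.
    """
    if not 1 <= w2 <= 7:
        raise ValueError(f"w2 must lie in 1..7, got {w2}")
    weights_1based = {1: 2, 2: w2, 3: 5, 4: 7, 5: 8, 6: 2, 7: 1}
    edges = [(i - 1, j - 1) for i, j in _EXAMPLE_EDGES_1BASED]
    weights = [weights_1based[k] for k in range(1, 8)]
    return build_graph(7, edges, weights)
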