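import pytest

from mwclique import GeneratorParams, example_graph, random_weighted_graph


@pytest.fixture
def fixture7():
    """The 7-vertex illustration graph (external vertex k = internal k-1)."""
    return example_graph()


def small_random_graph(n, p, seed, mu=1_000_000.0, sigma=200_000.0):
    return random_weighted_graph(
        GeneratorParams(n=n, p=p, mu=mu, sigma=sigma, seed=seed)
    )


def all_cliques(G, restrict=None):
    """Every nonempty clique of G (within `restrict`), by plain recursion."""
    verts = sorted(restrict) if restrict is not None else list(range(G.n))
    out = []

    def rec(clique, cand):
        for i, v in enumerate(cand):
            nxt = clique + [v]
            out.append(frozenset(nxt))
            rec(nxt, [u for u in cand[i + 1 :] if u in G.adjacency[v]])

    rec([], verts)
    return out
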