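import pytest

from mwclique import (
    brute_force_mwc,
    build_graph,
    max_clique_dyn_weight,
    max_clique_weight,
    relabel,
    shuffle_vertices,
    solve,
)

from conftest import all_cliques, small_random_graph


class TestWorkedExample:
    def test_optimum_and_incumbents(self, fixture7):
        r = max_clique_weight(fixture7)
        assert r.weight == 20
        assert sorted(v + 1 for v in r.clique) == [3, 4, 5]
        # first stored clique is {4,5,6,7} (weight 18), then the optimum
        assert r.incumbent_history == (18, 20)

    def test_partial_clique_weights_along_the_trace(self, fixture7):
        # the search passes through the grown clique {3, 5} of weight 13
        seen = []
        max_clique_weight(fixture7, observer=lambda lvl, p, wq: seen.append(wq))
        assert 13 in seen

    def test_branch_through_vertex_1_before_the_optimum_is_known(self, fixture7):
        # With Q = {3} (weight 5) and incumbent 18, vertex 1 passes the
        # bound (5 + 15 > 18) and grows Q to weight 7; its remaining
        # candidates {4, 2} then prune entirely (7 <= gap 11), killing the
        # branch.
        from mwclique import color_sort_weight

        assert fixture7.clique_weight([2, 0]) == 7  # vertices 3 and 1
        cs = color_sort_weight(fixture7, [3, 1], 7, 18)
        assert cs.wcolors == [0, 0]

    def test_dynamic_variant_agrees(self, fixture7):
        r = max_clique_dyn_weight(fixture7, tlimit=0.025)
        assert r.weight == 20 and sorted(v + 1 for v in r.clique) == [3, 4, 5]
        assert r.incumbent_history == (18, 20)


class TestTrivialGraphs:
    def test_complete_k4(self):
        G = build_graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)],
                        [1, 2, 3, 4])
        r = max_clique_weight(G)
        assert r.weight == 10 and sorted(r.clique) == [0, 1, 2, 3]

    def test_edgeless_picks_heaviest_vertex(self):
        G = build_graph(3, [], [3, 9, 2])
        r = max_clique_weight(G)
        assert r.weight == 9 and r.clique == (1,)

    def test_single_vertex(self):
        r = solve(build_graph(1, [], [5]), variant="static")
        assert r.weight == 5 and r.steps_total >= 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            max_clique_weight(build_graph(0, [], []))

    def test_bad_variant_and_tlimit_rejected(self, fixture7):
        with pytest.raises(ValueError):
            solve(fixture7, variant="magic")
        with pytest.raises(ValueError):
            max_clique_dyn_weight(fixture7, tlimit=1.5)


@pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
@pytest.mark.parametrize("seed", range(4))
def test_exactness_against_oracle(p, seed):
    """Both variants return the brute-force optimum, and a valid clique."""
    G = small_random_graph(12 + seed, p, 7000 + seed)
    expected = brute_force_mwc(G).weight
    for variant in ("static", "dynamic"):
        r = solve(G, variant=variant)
        assert r.weight == expected
        assert G.is_clique(r.clique)
        assert G.clique_weight(r.clique) == r.weight
        assert list(r.incumbent_history) == sorted(set(r.incumbent_history))
        assert r.incumbent_history[-1] == r.weight


@pytest.mark.parametrize("seed", range(5))
def test_tlimit_zero_reproduces_static_step_for_step(seed):
    """A closed gate makes the dynamic variant identical, counters included."""
    G = small_random_graph(20, 0.6, 300 + seed)
    a = max_clique_weight(G)
    b = max_clique_dyn_weight(G, tlimit=0.0)
    assert (a.clique, a.weight, a.steps_total, a.incumbent_history) == (
        b.clique, b.weight, b.steps_total, b.incumbent_history
    )


@pytest.mark.parametrize("seed", range(3))
def test_shuffle_invariance_small(seed):
    """Relabeling never changes the optimum weight."""
    G = small_random_graph(30, 0.6, 40 + seed)
    base = max_clique_weight(G).weight
    for k in range(20):
        H = shuffle_vertices(G, seed=1000 * seed + k)
        assert max_clique_weight(H).weight == base
        assert max_clique_dyn_weight(H).weight == base


@pytest.mark.parametrize("seed", range(3))
def test_unweighted_reduction_matches_clique_number(seed):
    """Unit weights turn the solver into a maximum clique cardinality solver."""
    networkx = pytest.importorskip("networkx")
    G = small_random_graph(20, 0.5, 900 + seed)
    G1 = build_graph(G.n, list(G.edges()), [1] * G.n)
    H = networkx.Graph()
    H.add_nodes_from(range(G.n))
    H.add_edges_from(G.edges())
    omega = max((len(c) for c in networkx.find_cliques(H)), default=1)
    assert max_clique_weight(G1).weight == omega


@pytest.mark.parametrize("seed", range(3))
def test_adding_an_edge_never_decreases_the_optimum(seed):
    G = small_random_graph(11, 0.4, 50 + seed, mu=60, sigma=25)
    base = max_clique_weight(G).weight
    missing = [
        (i, j)
        for i in range(G.n)
        for j in range(i + 1, G.n)
        if j not in G.adjacency[i]
    ]
    for extra in missing[:15]:
        H = build_graph(G.n, list(G.edges()) + [extra], list(G.weights))
        assert max_clique_weight(H).weight >= base


def test_cross_check_against_networkx_weighted(seed=0):
    """Independent weighted reference (library implementation) agrees."""
    networkx = pytest.importorskip("networkx")
    for s in range(5):
        G = small_random_graph(16, 0.6, 1234 + s, mu=500, sigma=150)
        H = networkx.Graph()
        for v in range(G.n):
            H.add_node(v, weight=G.weights[v])
        H.add_edges_from(G.edges())
        _, w = networkx.algorithms.clique.max_weight_clique(H, weight="weight")
        assert max_clique_weight(G).weight == w
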