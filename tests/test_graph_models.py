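"""Construction, temperature, enumeration and serialization of graph families."""

import itertools
from fractions import Fraction

import networkx as nx
import pytest

from moranfix import graph_models as gm


class TestGenerators:
    def test_complete_smallest_is_single_edge(self):
        g = gm.make_complete(2)
        assert sorted(g.edges) == [(0, 1)]
        assert [d for _, d in g.degree] == [1, 1]

    def test_complete_order6_edge_count(self):
        g = gm.make_complete(6)
        assert g.number_of_edges() == 15
        assert all(d == 5 for _, d in g.degree)

    def test_star_degree_sequence(self):
        g = gm.make_star(5)
        assert g.number_of_nodes() == 6
        assert sorted((d for _, d in g.degree), reverse=True) == [5, 1, 1, 1, 1, 1]

    def test_star_of_one_leaf_is_single_edge(self):
        assert gm.canonical_form(gm.make_star(1)) == gm.canonical_form(gm.make_complete(2))

    def test_bipartite_one_sided_is_star(self):
        assert gm.canonical_form(gm.make_complete_bipartite(1, 4)) == gm.canonical_form(
            gm.make_star(4)
        )

    def test_bipartite_degrees(self):
        g = gm.make_complete_bipartite(2, 3)
        assert sorted((d for _, d in g.degree), reverse=True) == [3, 3, 2, 2, 2]

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_ell_graph_structure(self, n):
        g = gm.make_ell_graph(n)
        N = 2 * n + 2
        assert g.number_of_nodes() == N
        # clique vertices have degree 2n, the two extra vertices n+1
        degs = sorted(d for _, d in g.degree)
        assert degs == [n + 1] * 2 + [2 * n] * 2 * n
        # C(2n,2) clique edges + 2n spokes + the u-v bridge
        assert g.number_of_edges() == n * (2 * n - 1) + 2 * n + 1

    def test_ell_graph_swap_is_automorphism(self):
        n = 3
        g = gm.make_ell_graph(n)
        swap = {i: i + n if i < n else i - n for i in range(2 * n)}
        swap[2 * n] = 2 * n + 1
        swap[2 * n + 1] = 2 * n
        mapped = {tuple(sorted((swap[a], swap[b]))) for a, b in g.edges}
        assert mapped == {tuple(sorted(e)) for e in g.edges}

    def test_unbalanced_extra_degrees(self):
        g = gm.make_unbalanced_ell(6, 1, 3)
        assert g.degree(4) == 2 and g.degree(5) == 4  # u sees 1 clique vertex + v
        assert sorted(d for _, d in g.degree) == [2, 4, 4, 4, 4, 4]

    def test_balanced_split_matches_ell_graph(self):
        assert gm.canonical_form(gm.make_unbalanced_ell(6, 2, 2)) == gm.canonical_form(
            gm.make_ell_graph(2)
        )

    @pytest.mark.parametrize(
        "fn,args",
        [
            (gm.make_complete, (1,)),
            (gm.make_star, (0,)),
            (gm.make_ell_graph, (1,)),
            (gm.make_complete_bipartite, (0, 3)),
            (gm.make_unbalanced_ell, (7, 2, 2)),
        ],
    )
    def test_invalid_parameters_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    @pytest.mark.parametrize("maker", [gm.make_complete, gm.make_star, gm.make_ell_graph])
    def test_generated_graphs_validate(self, maker):
        g = maker(4)
        gm.validate_graph(g)  # no self-loops, connected, labels 0..N-1


class TestTemperature:
    def test_complete_graph_temperature_one(self):
        g = gm.make_complete(7)
        assert all(gm.vertex_temperature(g, i) == 1 for i in g.nodes)

    def test_star_center_and_leaf(self, star3):
        assert gm.vertex_temperature(star3, 0) == 3
        assert gm.vertex_temperature(star3, 1) == Fraction(1, 3)

    def test_ell6_extra_vertex(self, ell6):
        # u's neighbors: two clique vertices of degree 4 and v of degree 3
        assert gm.vertex_temperature(ell6, 4) == Fraction(5, 6)

    def test_isothermal_families(self, ell6):
        assert gm.is_isothermal(gm.make_complete(4))
        assert gm.is_isothermal(nx.cycle_graph(5))
        assert gm.is_isothermal(gm.make_complete_bipartite(2, 2))
        assert not gm.is_isothermal(ell6)
        assert not gm.is_isothermal(gm.make_star(3))

    def test_invalid_vertex(self, ell6):
        with pytest.raises(ValueError):
            gm.vertex_temperature(ell6, 99)


def _brute_force_classes(N):
    """All connected isomorphism classes by filtering every labeled graph."""
    pairs = list(itertools.combinations(range(N), 2))
    seen = set()
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(N))
        g.add_edges_from(p for p, b in zip(pairs, bits) if b)
        if all(d > 0 for _, d in g.degree) and nx.is_connected(g):
            seen.add(gm.canonical_form(g))
    return seen


class TestEnumeration:
    @pytest.mark.parametrize("N,count", [(2, 1), (3, 2), (4, 6), (5, 21), (6, 112), (7, 853)])
    def test_connected_class_counts(self, N, count):
        graphs = gm.enumerate_connected_graphs(N)
        assert len(graphs) == count
        for g in graphs:
            gm.validate_graph(g)

    @pytest.mark.parametrize("N", [3, 4, 5])
    def test_agrees_with_brute_force_oracle(self, N):
        enumerated = {gm.canonical_form(g) for g in gm.enumerate_connected_graphs(N)}
        assert enumerated == _brute_force_classes(N)

    def test_order6_contains_ell_graph(self, ell6):
        target = gm.canonical_form(ell6)
        assert any(gm.canonical_form(g) == target for g in gm.enumerate_connected_graphs(6))

    def test_large_orders_refused(self):
        with pytest.raises(ValueError):
            gm.enumerate_connected_graphs(8)


class TestEdgeList:
    def test_round_trip(self, tmp_path, ell6):
        path = tmp_path / "g.txt"
        gm.write_edgelist(ell6, path)
        g2 = gm.read_edgelist(path)
        assert set(map(frozenset, g2.edges)) == set(map(frozenset, ell6.edges))

    def test_reader_rejects_self_loop(self):
        with pytest.raises(ValueError, match="self-loop"):
            gm.read_edgelist(["0 1", "2 2"])

    def test_reader_rejects_malformed_line(self):
        with pytest.raises(ValueError, match="two vertex ids"):
            gm.read_edgelist(["0 1 2"])

    def test_reader_skips_comments(self):
        g = gm.read_edgelist(["# a comment", "", "0 1", "1 2"])
        assert g.number_of_edges() == 2
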