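import networkx as nx
import numpy as np
import pytest

from gfsn import RganConfig, build_rgan, ecc_weights, integrate_ppi, topo_index
from gfsn.rgan import INDEX_NAMES

from .conftest import random_graph, random_weighted_graph
from .oracles import ecc_oracle, index_oracle


def unit_graph(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=1.0)
    return g


class TestIntegratePPI:
    def test_union_over_universe(self):
        a, b = unit_graph([("a", "b")]), unit_graph([("b", "c")])
        g = integrate_ppi([a, b], {"a", "b", "c"})
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("bc")}
        assert all(w == 1.0 for _, _, w in g.edges(data="weight"))

    def test_idempotent_union(self):
        a = unit_graph([("a", "b"), ("b", "c")])
        g = integrate_ppi([a, a.copy()], {"a", "b", "c"})
        assert g.number_of_edges() == 2

    def test_universe_restriction_drops_edges(self):
        a = unit_graph([("a", "b"), ("b", "c")])
        g = integrate_ppi([a], {"a", "b"})
        assert set(map(frozenset, g.edges)) == {frozenset("ab")}

    def test_empty_union_is_error(self):
        with pytest.raises(ValueError):
            integrate_ppi([unit_graph([("a", "b")])], {"x", "y"})


class TestEccWeights:
    def test_triangle_edge_is_one(self):
        g = ecc_weights(unit_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        assert all(w == 1.0 for _, _, w in g.edges(data="weight"))

    def test_zero_denominator_convention(self, path_graph):
        g = ecc_weights(path_graph)
        assert g["a"]["b"]["weight"] == 0.0

    def test_complete_graphs_all_one(self):
        for n in (3, 4, 6):
            g = ecc_weights(nx.complete_graph(n))
            assert all(w == 1.0 for _, _, w in g.edges(data="weight"))

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            g = random_graph(rng)
            got = ecc_weights(g)
            for x, y in g.edges:
                assert got[x][y]["weight"] == pytest.approx(ecc_oracle(g, x, y), abs=1e-12)
            assert all(0.0 <= w <= 1.0 for _, _, w in got.edges(data="weight"))


class TestTopoIndices:
    def test_single_path_hand_values(self):
        g = unit_graph([("x", "z"), ("z", "y")])
        assert topo_index(g, "WCN")[("x", "y")] == pytest.approx(2.0)
        assert topo_index(g, "rWCN")[("x", "y")] == pytest.approx(1.0)
        assert topo_index(g, "WRA")[("x", "y")] == pytest.approx(1.0)  # s_z = 2

    def test_no_common_neighbour_no_path_scores_zero(self):
        g = unit_graph([("x", "a"), ("y", "b")])
        for name in INDEX_NAMES:
            assert ("x", "y") not in topo_index(g, name)

    def test_lp_adds_half_the_length3_path_count(self):
        # x-m, m-n, n-y: one simple length-3 path between x and y
        g = unit_graph([("x", "m"), ("m", "n"), ("n", "y")])
        got = topo_index(g, "rWCNLP", RganConfig(alpha_path=0.5))
        assert got[("x", "y")] == pytest.approx(0.5)

    def test_lp_equals_reliable_route_when_alpha_zero(self, rng):
        g = random_weighted_graph(rng)
        cfg = RganConfig(alpha_path=0.0)
        for base, lp in (("rWCN", "rWCNLP"), ("rWRA", "rWRALP"), ("rWAA", "rWAALP")):
            assert topo_index(g, base, cfg) == topo_index(g, lp, cfg)

    def test_unweighted_identities(self, rng):
        """With unit weights WCN = 2|O_xy| and rWCN = |O_xy| exactly."""
        for _ in range(20):
            g = random_graph(rng)
            wcn, rwcn = topo_index(g, "WCN"), topo_index(g, "rWCN")
            nodes = sorted(g.nodes)
            for i, x in enumerate(nodes):
                for y in nodes[i + 1:]:
                    o = len(set(g[x]) & set(g[y]))
                    key = (x, y)
                    assert wcn.get(key, 0.0) == pytest.approx(2.0 * o)
                    assert rwcn.get(key, 0.0) == pytest.approx(float(o))

    @pytest.mark.parametrize("index", INDEX_NAMES)
    def test_matches_brute_force_enumeration(self, rng, index):
        for _ in range(25):
            g = random_weighted_graph(rng, n_max=20)
            got = topo_index(g, index)
            nodes = sorted(g.nodes)
            for i, x in enumerate(nodes):
                for y in nodes[i + 1:]:
                    want = index_oracle(g, x, y, index)
                    assert got.get((x, y), 0.0) == pytest.approx(want, abs=1e-10)

    def test_scores_symmetric_and_nonnegative(self, rng):
        g = random_weighted_graph(rng)
        for name in INDEX_NAMES:
            for (a, b), v in topo_index(g, name).items():
                assert a < b and v >= 0.0

    def test_lp_only_unconnected_zeroes_adjacent_path_terms(self):
        g = unit_graph([("x", "y"), ("x", "m"), ("m", "n"), ("n", "y")])
        cfg = RganConfig(lp_only_unconnected=True)
        base = topo_index(g, "rWCN", cfg)
        lp = topo_index(g, "rWCNLP", cfg)
        assert lp.get(("x", "y"), 0.0) == base.get(("x", "y"), 0.0)


class TestBuildRgan:
    @staticmethod
    def k3():
        return ecc_weights(nx.relabel_nodes(nx.complete_graph(3), str))

    def test_k3_symmetry(self):
        rgan = build_rgan(self.k3())
        vals = {rgan.get(a, b) for a, b in [("0", "1"), ("0", "2"), ("1", "2")]}
        assert len({round(v, 12) for v in vals}) == 1

    def test_one_hot_weights_give_normalized_single_index(self, rng):
        g = ecc_weights(random_graph(rng))
        weights = [0.0] * 9
        weights[0] = 1.0  # WCN
        rgan = build_rgan(g, RganConfig(index_weights=weights))
        table = topo_index(g, "WCN")
        m = max(table.values())
        for (a, b), v in table.items():
            assert rgan.get(a, b) == pytest.approx(v / m, abs=1e-12)

    def test_identical_tables_fixed_point(self):
        # On K3 with ECC weights every index table is constant over the three
        # pairs, so max-normalization sends each to 1 and the combination is 1.
        rgan = build_rgan(self.k3())
        assert rgan.get("0", "1") == pytest.approx(1.0)

    def test_output_in_unit_interval_and_symmetric(self, rng):
        g = ecc_weights(random_graph(rng))
        rgan = build_rgan(g)
        assert np.all(rgan.values >= 0) and np.all(rgan.values <= 1)
        np.testing.assert_array_equal(rgan.values, rgan.values.T)

    def test_order_of_index_weights_respected(self, rng):
        g = ecc_weights(random_graph(rng))
        a = build_rgan(g, RganConfig())
        b = build_rgan(g, RganConfig(index_weights=[1 / 9.0] * 9))
        np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_rank_normalization_bounded(self, rng):
        g = ecc_weights(random_graph(rng))
        rgan = build_rgan(g, RganConfig(normalize="rank"))
        assert np.all(rgan.values <= 1.0 + 1e-12)
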