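import numpy as np
import pytest

from sfnet import oracles
from sfnet.clustering import (
    ClusteringResult,
    average,
    clustering_binary,
    clustering_multiplex_weighted,
    clustering_weighted,
    jaccard_weighted,
    sf_clustering_binary,
    sf_clustering_weighted,
)
from sfnet.netmodel import LayerMatrix, MultiplexNetwork

from conftest import random_layer


class TestSingleLayer:
    def test_complete_graph_fully_clustered(self, k3):
        for fn in (clustering_binary, clustering_weighted):
            res = fn(k3)
            assert res.per_node.tolist() == [1.0, 1.0, 1.0]
            assert res.mean == 1.0

    def test_path_has_no_triangles(self, path3):
        assert clustering_binary(path3).per_node.tolist() == [0.0, 0.0, 0.0]

    def test_weighted_triangle_hand_value(self, weighted_triangle):
        # node 0: numerator 2 * (0.5 * 0.8 * 0.5) = 0.4,
        #         denominator 2 * (0.5 * 0.5) = 0.5  ->  0.8
        res = clustering_weighted(weighted_triangle)
        assert res.per_node[0] == pytest.approx(0.8, abs=1e-15)

    def test_binary_requires_binary(self, weighted_triangle):
        with pytest.raises(ValueError, match="binary"):
            clustering_binary(weighted_triangle)

    def test_erdos_renyi_matches_enumeration(self):
        layer = random_layer(np.random.default_rng(8), 8, density=0.5, binary=True)
        res = clustering_binary(layer)
        ref = oracles.clustering_binary_oracle(layer.weights)
        np.testing.assert_allclose(res.per_node, ref, atol=1e-12, rtol=0)

    def test_weighted_matches_enumeration(self):
        layer = random_layer(np.random.default_rng(12), 12, density=0.7)
        res = clustering_weighted(layer)
        ref = oracles.clustering_weighted_oracle(layer.weights)
        np.testing.assert_allclose(res.per_node, ref, atol=1e-12, rtol=0)

    def test_binary_reduction_exact(self, rng):
        layer = random_layer(rng, 11, density=0.4, binary=True)
        assert np.array_equal(
            clustering_weighted(layer).per_node,
            clustering_binary(layer).per_node,
        )

    def test_isolated_and_degree_one_nodes_get_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0  # nodes 2, 3 isolated; 0, 1 degree one
        res = clustering_binary(LayerMatrix(w))
        assert res.per_node.tolist() == [0.0] * 4
        assert res.mean == 0.0


class TestMultiplex:
    def test_two_identical_layers_reduce_exactly(self, rng):
        layer = random_layer(rng, 9, density=0.6)
        mx = MultiplexNetwork([layer, layer])
        assert np.array_equal(
            clustering_multiplex_weighted(mx).per_node,
            clustering_weighted(layer).per_node,
        )

    @pytest.mark.parametrize("m", [3, 4])
    def test_m_identical_layers_reduce(self, rng, m):
        # re-association of identical sums costs at most one ulp
        layer = random_layer(rng, 9, density=0.6)
        mx = MultiplexNetwork([layer] * m)
        np.testing.assert_allclose(
            clustering_multiplex_weighted(mx).per_node,
            clustering_weighted(layer).per_node,
            rtol=5e-16, atol=0,
        )

    def test_three_binary_layers_match_enumeration(self):
        rng = np.random.default_rng(42)
        layers = [random_layer(rng, 10, density=0.4, binary=True) for _ in range(3)]
        mx = MultiplexNetwork(layers)
        ref = oracles.clustering_multiplex_oracle(
            np.stack([lay.weights for lay in layers])
        )
        np.testing.assert_allclose(
            clustering_multiplex_weighted(mx).per_node, ref, atol=1e-12, rtol=0
        )

    def test_empty_layer_annihilates_its_terms(self, rng):
        layer = random_layer(rng, 8, density=0.6)
        empty = LayerMatrix(np.zeros((8, 8)))
        # numerator: only the wings-in-nonzero-layer term survives; an empty
        # closing layer kills it too, so the coefficient is identically zero
        res = clustering_multiplex_weighted(MultiplexNetwork([layer, empty]))
        assert res.per_node.tolist() == [0.0] * 8

    def test_single_layer_rejected(self, k3):
        with pytest.raises(ValueError, match="2 layers"):
            clustering_multiplex_weighted(MultiplexNetwork([k3]))


class TestStructureFunction:
    def test_identical_layers_give_zero(self, rng):
        layer = random_layer(rng, 10, density=0.5, binary=True)
        res = sf_clustering_binary(layer, layer)
        assert res.per_node.tolist() == [0.0] * 10

    def test_structural_tuple_closed_by_functional_edge(self):
        # structural path 1-0-2, functional edge {1,2}: the single structural
        # tuple at node 0 is functionally closed -> coefficient 1
        sc = np.zeros((3, 3))
        sc[0, 1] = sc[1, 0] = sc[0, 2] = sc[2, 0] = 1.0
        fc = np.zeros((3, 3))
        fc[1, 2] = fc[2, 1] = 1.0
        res = sf_clustering_binary(LayerMatrix(sc), LayerMatrix(fc))
        assert res.per_node[0] == 1.0

    def test_weighted_hand_value(self):
        # structural path 1-0-2 with w = 0.6, functional edge w12 = 0.9:
        # numerator 2 * 0.6 * 0.9 * 0.6, denominator 0.72 * 1 -> 0.9
        sc = np.zeros((3, 3))
        sc[0, 1] = sc[1, 0] = sc[0, 2] = sc[2, 0] = 0.6
        fc = np.zeros((3, 3))
        fc[1, 2] = fc[2, 1] = 0.9
        res = sf_clustering_weighted(LayerMatrix(sc), LayerMatrix(fc))
        assert res.per_node[0] == pytest.approx(0.9, abs=1e-15)

    @pytest.mark.parametrize("binary", [True, False])
    def test_random_pair_matches_enumeration(self, binary):
        rng = np.random.default_rng(77)
        sc = random_layer(rng, 12 if not binary else 10, density=0.5, binary=binary)
        fc = random_layer(rng, sc.n_nodes, density=0.5, binary=binary)
        fn = sf_clustering_binary if binary else sf_clustering_weighted
        res = fn(sc, fc)
        ref = oracles.sf_clustering_oracle(sc.weights, fc.weights)
        np.testing.assert_allclose(res.per_node, ref, atol=1e-12, rtol=0)

    def test_binary_reduction_exact(self, rng):
        sc = random_layer(rng, 10, density=0.5, binary=True)
        fc = random_layer(rng, 10, density=0.5, binary=True)
        assert np.array_equal(
            sf_clustering_weighted(sc, fc).per_node,
            sf_clustering_binary(sc, fc).per_node,
        )

    def test_shape_mismatch_rejected(self, k3):
        with pytest.raises(ValueError, match="mismatch"):
            sf_clustering_weighted(k3, LayerMatrix(np.zeros((4, 4))))


class TestJaccard:
    def test_self_similarity_is_one(self, rng):
        layer = random_layer(rng, 8, density=0.5)
        assert jaccard_weighted(layer, layer) == 1.0

    def test_binary_edge_set_jaccard(self):
        def from_edges(edges, n=4):
            w = np.zeros((n, n))
            for i, j in edges:
                w[i, j] = w[j, i] = 1.0
            return LayerMatrix(w)

        a = from_edges([(0, 1), (1, 2)])
        b = from_edges([(1, 2), (2, 3)])
        assert jaccard_weighted(a, b) == pytest.approx(1 / 3)

    def test_hand_summed_min_max(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.4
        a[1, 2] = a[2, 1] = 0.2
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = 0.8
        b[1, 2] = b[2, 1] = 0.2
        b[0, 2] = b[2, 0] = 0.5
        val = jaccard_weighted(LayerMatrix(a), LayerMatrix(b))
        assert val == pytest.approx((0.4 + 0.2) / (0.8 + 0.2 + 0.5))

    def test_symmetry_and_oracle(self, rng):
        a = random_layer(rng, 9, density=0.5)
        b = random_layer(rng, 9, density=0.5)
        j1 = jaccard_weighted(a, b)
        assert j1 == jaccard_weighted(b, a)
        assert j1 == pytest.approx(
            oracles.jaccard_oracle(a.weights, b.weights), abs=1e-12
        )
        assert 0.0 <= j1 <= 1.0

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        b = np.zeros((3, 3))
        b[1, 2] = b[2, 1] = 0.5
        assert jaccard_weighted(LayerMatrix(a), LayerMatrix(b)) == 0.0

    def test_all_zero_pair_rejected(self):
        z = LayerMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="all-zero"):
            jaccard_weighted(z, z)

    def test_literal_sum_of_ratios_variant(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = 1.0
        val = jaccard_weighted(LayerMatrix(a), LayerMatrix(b),
                               variant="sum-of-ratios")
        assert val == pytest.approx(1.0)  # two ordered entries at ratio 0.5


class TestResultContainer:
    def test_mean_is_node_average(self):
        res = ClusteringResult(np.array([0.2, 0.4, 0.9]), "weighted")
        assert res.mean == pytest.approx(0.5)
        assert average(res) == res.mean

    def test_permutation_equivariance(self, rng):
        layer = random_layer(rng, 10, density=0.5)
        other = random_layer(rng, 10, density=0.5)
        perm = rng.permutation(10)
        p_layer = LayerMatrix(layer.weights[np.ix_(perm, perm)])
        p_other = LayerMatrix(other.weights[np.ix_(perm, perm)])
        for fn in (clustering_weighted,):
            np.testing.assert_allclose(
                fn(p_layer).per_node, fn(layer).per_node[perm], atol=1e-12
            )
        np.testing.assert_allclose(
            sf_clustering_weighted(p_layer, p_other).per_node,
            sf_clustering_weighted(layer, other).per_node[perm],
            atol=1e-12,
        )
        assert jaccard_weighted(p_layer, p_other) == pytest.approx(
            jaccard_weighted(layer, other), abs=1e-12
        )
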