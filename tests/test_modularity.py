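"""Null model exactness, modularity identities, and cross-checks.

The single-layer quality function is cross-checked against python-igraph's
weighted modularity (an independent implementation of the same
configuration-null quantity, up to the 1/2m normalization igraph applies).
"""

import numpy as np
import pytest

from multifreq import (
    MultilayerNetwork,
    Partition,
    QualityParams,
    layerwise_strengths,
    modularity_matrix,
    multilayer_modularity,
    null_expectation,
    singlelayer_modularity,
)
from multifreq.modularity import null_block

from conftest import random_multilayer


class TestNullModel:
    def test_single_intra_edge_forced_value(self):
        net = MultilayerNetwork(
            ["h"], [2], intra={0: np.array([[0.0, 2.0], [2.0, 0.0]])}
        )
        st = layerwise_strengths(net)
        # s_u = s_v = 2, m = 2: P = 2*2 / (2*2) = 1
        assert null_expectation(st, 0, 0, 1, 0) == pytest.approx(1.0)

    def test_single_inter_edge_forced_value(self, toy_net):
        st = layerwise_strengths(toy_net)
        # s = 0.5 on both ends, m = 0.5: P = 0.25 / 0.5 = 0.5
        assert null_expectation(st, 0, 0, 0, 1) == pytest.approx(0.5)
        # symmetric in (u, h) <-> (v, k)
        assert null_expectation(st, 0, 1, 0, 0) == pytest.approx(0.5)

    def test_empty_block_gives_zero(self):
        net = MultilayerNetwork(["a", "b"], [2, 2])
        st = layerwise_strengths(net)
        assert null_expectation(st, 0, 0, 1, 1) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_marginals_preserve_strengths(self, seed):
        net = random_multilayer(seed, n_layers=3, n_nodes=6)
        st = layerwise_strengths(net)
        for h in range(3):
            for k in range(3):
                P = null_block(st, h, k)
                assert np.allclose(P.sum(axis=1), st.s[(h, k)], atol=1e-12)


class TestMultilayerModularity:
    def test_all_in_one_is_zero_at_unit_resolution(self):
        for seed in range(5):
            net = random_multilayer(seed, n_layers=3, n_nodes=5)
            part = Partition(net, np.zeros(net.n_total, dtype=int))
            for omega in (0.0, 0.5, 2.0):
                q = multilayer_modularity(net, part, QualityParams(1.0, omega))
                assert abs(q) < 1e-9

    def test_omega_zero_decomposes_over_layers(self):
        net = random_multilayer(11, n_layers=3, n_nodes=5)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=net.n_total)
        q_ml = multilayer_modularity(net, Partition(net, labels), QualityParams(1.3, 0.0))
        off = net.layer_offsets()
        q_layers = sum(
            singlelayer_modularity(net.intra_block(h), labels[off[h]:off[h + 1]], 1.3)
            for h in range(3)
        )
        assert q_ml == pytest.approx(q_layers, abs=1e-9)

    def test_label_and_node_permutation_invariance(self):
        net = random_multilayer(5, n_layers=2, n_nodes=5)
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=net.n_total)
        params = QualityParams(1.1, 0.7)
        q = multilayer_modularity(net, Partition(net, labels), params)
        relabeled = np.array([{0: 7, 1: 2, 2: 5}[g] for g in labels])
        assert multilayer_modularity(net, Partition(net, relabeled), params) == \
            pytest.approx(q, abs=1e-9)
        # permuting node ids consistently across network and partition
        perm = rng.permutation(5)
        intra = {h: net.intra_block(h)[np.ix_(perm, perm)] for h in range(2)}
        inter = {(0, 1): net.inter_block(0, 1)[np.ix_(perm, perm)]}
        net_p = MultilayerNetwork(net.layers, net.n_nodes, intra, inter)
        labels_p = np.concatenate([labels[:5][perm], labels[5:][perm]])
        assert multilayer_modularity(net_p, Partition(net_p, labels_p), params) == \
            pytest.approx(q, abs=1e-9)

    def test_planted_partition_beats_random(self, planted_two_cliques):
        net, planted = planted_two_cliques
        params = QualityParams(1.0, 1.0)
        q_planted = multilayer_modularity(net, planted, params)
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = rng.integers(0, 4, size=net.n_total)
            assert multilayer_modularity(net, Partition(net, labels), params) < q_planted

    def test_increasing_gamma_strictly_decreases_q(self):
        net = random_multilayer(2, n_layers=2, n_nodes=5)
        labels = np.array([0, 0, 1, 1, 2] * 2)
        qs = [
            multilayer_modularity(net, Partition(net, labels), QualityParams(g, 0.5))
            for g in (0.8, 1.0, 1.2, 1.5)
        ]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_partition_must_cover_network(self):
        net = random_multilayer(0)
        with pytest.raises(ValueError):
            Partition(net, np.zeros(net.n_total - 1, dtype=int))

    def test_modularity_matrix_quadratic_form_matches(self):
        net = random_multilayer(9, n_layers=3, n_nodes=4)
        params = QualityParams(0.97, 0.3)
        B = modularity_matrix(net, params)
        assert np.allclose(B, B.T, atol=1e-12)
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=net.n_total)
        same = labels[:, None] == labels[None, :]
        assert B[same].sum() == pytest.approx(
            multilayer_modularity(net, Partition(net, labels), params), abs=1e-9
        )


class TestSingleLayerModularity:
    def test_all_in_one_zero(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0, 1, (6, 6))
        A = np.triu(A, 1)
        A = A + A.T
        assert singlelayer_modularity(A, np.zeros(6, int), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_hand_value(self):
        # two disconnected triangles, unit weights: m = 6 edges... here 2*3 = 6
        # within-community weight sum = 2*6; s_i = 2 for all; P_ij = 4/12
        # Q = sum_{same community} (A_ij - P_ij) = (12 - 12*(1/3)) - 6*(1/3)... hand:
        # per clique: sum A = 6 (off-diag pairs, both orders) ; sum P over 3x3 block
        # = 9 * 4/12 = 3 ; Q = 2 * (6 - 3) = 6
        A = np.zeros((6, 6))
        for group in (range(3), range(3, 6)):
            for i in group:
                for j in group:
                    if i != j:
                        A[i, j] = 1.0
        q = singlelayer_modularity(A, [0, 0, 0, 1, 1, 1], 1.0)
        assert q == pytest.approx(6.0, abs=1e-12)

    def test_empty_graph_is_zero(self):
        assert singlelayer_modularity(np.zeros((4, 4)), [0, 1, 0, 1]) == 0.0

    @pytest.mark.parametrize("gamma", [0.8, 1.0, 1.3])
    def test_matches_igraph_weighted_modularity(self, gamma):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, (10, 10)) * (rng.random((10, 10)) < 0.5)
        A = np.triu(A, 1)
        A = A + A.T
        labels = rng.integers(0, 3, size=10)
        g = igraph.Graph.Weighted_Adjacency(A.tolist(), mode="undirected")
        q_ig = g.modularity(labels.tolist(), weights="weight", resolution=gamma)
        two_m = A.sum()
        assert singlelayer_modularity(A, labels, gamma) == pytest.approx(
            q_ig * two_m, rel=1e-9
        )

    def test_agrees_with_multilayer_on_one_layer(self):
        rng = np.random.default_rng(12)
        A = rng.uniform(0, 1, (7, 7))
        A = np.triu(A, 1)
        A = A + A.T
        net = MultilayerNetwork(["only"], [7], intra={0: A})
        labels = rng.integers(0, 3, size=7)
        for omega in (0.0, 0.9):
            assert multilayer_modularity(
                net, Partition(net, labels), QualityParams(1.2, omega)
            ) == pytest.approx(singlelayer_modularity(A, labels, 1.2), abs=1e-9)
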