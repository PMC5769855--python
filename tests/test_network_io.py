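import numpy as np
import pytest
from hypothesis import given, strategies as st

import cliquecav as cc
from cliquecav.network import NetworkError, load_network, save_network

from conftest import net_from_edges


class TestWeightedNetwork:
    def test_strengths_and_edge_count(self):
        net = cc.WeightedNetwork([[0, 2, 0], [2, 0, 1], [0, 1, 0]])
        assert net.n_edges == 2
        assert np.allclose(net.strengths, [2, 3, 1])

    def test_asymmetric_input_rejected(self):
        w = np.zeros((3, 3))
        w[1, 2], w[2, 1] = 5, 4
        with pytest.raises(NetworkError, match="asymmetric"):
            cc.WeightedNetwork(w)

    def test_zero_matrix_is_valid_empty_network(self):
        net = cc.WeightedNetwork(np.zeros((4, 4)))
        assert net.n_edges == 0 and net.n_nodes == 4

    @pytest.mark.parametrize(
        "bad",
        [
            np.full((2, 3), 1.0),  # non-square
            np.array([[0.0, -1.0], [-1.0, 0.0]]),  # negative
            np.eye(3),  # nonzero diagonal
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(NetworkError):
            cc.WeightedNetwork(bad)

    def test_metadata_count_mismatch(self):
        import pandas as pd

        with pytest.raises(NetworkError, match="metadata"):
            cc.WeightedNetwork(np.zeros((3, 3)), metadata=pd.DataFrame({"id": [1, 2]}))


class TestIO:
    def test_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        w = np.triu(rng.random((6, 6)), 1)
        net = cc.WeightedNetwork(w + w.T)
        save_network(net, tmp_path / "a.csv")
        back = load_network(tmp_path / "a.csv")
        assert np.array_equal(back.weights, net.weights)
        assert back.node_ids == net.node_ids

    def test_headerless_whitespace_matrix(self, tmp_path):
        (tmp_path / "m.txt").write_text("0 1\n1 0\n")
        net = load_network(tmp_path / "m.txt")
        assert net.n_edges == 1

    def test_metadata_aligned_by_id(self, tmp_path):
        save_network(net_from_edges(2, {(0, 1): 3.0}), tmp_path / "m.csv")
        (tmp_path / "meta.csv").write_text(
            "id,name,x,y,z,system\nn1,B,0,0,1,vis\nn0,A,0,0,0,dmn\n"
        )
        net = load_network(tmp_path / "m.csv", tmp_path / "meta.csv")
        assert list(net.metadata["name"]) == ["A", "B"]
        assert net.systems() == {0: "dmn", 1: "vis"}


class TestThreshold:
    def test_k4_half_density_keeps_top_three(self):
        net = net_from_edges(
            4, {(0, 1): 6, (0, 2): 5, (0, 3): 4, (1, 2): 3, (1, 3): 2, (2, 3): 1}
        )
        t = cc.threshold_by_density(net, 0.5)
        assert t.retained_edges == [(0, 1), (0, 2), (0, 3)]

    def test_lausanne_scale_edge_count(self):
        _, net = cc.random_geometric_network(83, seed=0)
        t = cc.threshold_by_density(net, 0.25)
        assert len(t.retained_edges) == 850  # floor(0.25 * 83*82/2)

    def test_boundary_densities(self):
        net = net_from_edges(4, {(0, 1): 2, (1, 2): 1})
        assert len(cc.threshold_by_density(net, 1.0).retained_edges) == 2
        assert cc.threshold_by_density(net, 0.0).retained_edges == []

    def test_strict_mode_rejects_tie_at_cut(self):
        net = net_from_edges(3, {(0, 1): 2, (0, 2): 1, (1, 2): 1})
        with pytest.raises(ValueError, match="tie"):
            cc.threshold_by_density(net, 2 / 3, tiebreak="strict")

    def test_every_retained_weight_dominates_discarded(self):
        rng = np.random.default_rng(1)
        net = cc.WeightedNetwork(
            (lambda u: u + u.T)(np.triu(rng.random((10, 10)), 1))
        )
        t = cc.threshold_by_density(net, 0.3)
        kept = {net.weights[e] for e in t.retained_edges}
        dropped = [w for _, _, w in net.edges() if w not in kept]
        assert min(kept) >= max(dropped)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_rho(self, r1, r2):
        rng = np.random.default_rng(7)
        net = cc.WeightedNetwork((lambda u: u + u.T)(np.triu(rng.random((8, 8)), 1)))
        lo, hi = sorted([r1, r2])
        a = set(cc.threshold_by_density(net, lo).retained_edges)
        b = set(cc.threshold_by_density(net, hi).retained_edges)
        assert a <= b


class TestTiebreakNoise:
    def test_makes_weights_distinct_within_epsilon(self):
        net = net_from_edges(3, {(0, 1): 2, (0, 2): 2, (1, 2): 1})
        out = cc.add_tiebreak_noise(net, epsilon=1e-4, seed=0)
        ws = [w for _, _, w in out.edges()]
        assert len(set(ws)) == 3
        for (i, j, w0), w1 in zip(net.edges(), ws):
            assert 0 <= w1 - w0 <= 1e-4

    def test_deterministic_given_seed(self):
        net = net_from_edges(3, {(0, 1): 2, (0, 2): 2, (1, 2): 1})
        a = cc.add_tiebreak_noise(net, seed=42)
        b = cc.add_tiebreak_noise(net, seed=42)
        assert np.array_equal(a.weights, b.weights)

    def test_zero_epsilon_rejected(self):
        with pytest.raises(ValueError):
            cc.add_tiebreak_noise(net_from_edges(2, {(0, 1): 1}), epsilon=0.0)


class TestGroupAverage:
    def test_mean_includes_absent_edges_as_zero(self):
        a = net_from_edges(3, {(0, 1): 2, (0, 2): 6})
        b = net_from_edges(3, {(0, 1): 4})
        avg = cc.group_average([a, b])
        assert avg.weights[0, 1] == 3
        assert avg.weights[0, 2] == 3

    def test_single_network_identity(self):
        a = net_from_edges(3, {(0, 1): 2})
        assert np.array_equal(cc.group_average([a]).weights, a.weights)

    def test_node_set_mismatch_rejected(self):
        a = cc.WeightedNetwork(np.zeros((2, 2)), node_ids=["a", "b"])
        b = cc.WeightedNetwork(np.zeros((2, 2)), node_ids=["b", "a"])
        with pytest.raises(NetworkError):
            cc.group_average([a, b])

    @given(st.permutations(range(5)))
    def test_commutes_with_consistent_reordering(self, perm):
        rng = np.random.default_rng(3)
        mats = [
            (lambda u: u + u.T)(np.triu(rng.random((5, 5)), 1)) for _ in range(3)
        ]
        perm = list(perm)
        ids = [f"n{i}" for i in range(5)]
        avg_then_perm = cc.group_average(
            [cc.WeightedNetwork(m, ids) for m in mats]
        ).weights[np.ix_(perm, perm)]
        perm_then_avg = cc.group_average(
            [
                cc.WeightedNetwork(m[np.ix_(perm, perm)], [ids[p] for p in perm])
                for m in mats
            ]
        ).weights
        assert np.allclose(avg_then_perm, perm_then_avg)
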