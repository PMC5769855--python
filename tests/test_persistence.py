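import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cliquecav as cc
from cliquecav.persistence import (
    betti_numbers_at,
    build_filtration,
    euler_characteristic_check,
    persistent_homology,
)

from conftest import net_from_edges, random_er_network


class TestFiltration:
    def test_densities_count_all_pairs(self):
        net = net_from_edges(3, {(0, 1): 5, (0, 2): 3, (1, 2): 1})
        f = build_filtration(net)
        assert [f.density(s) for s in (1, 2, 3)] == [
            pytest.approx(1 / 3),
            pytest.approx(2 / 3),
            pytest.approx(1.0),
        ]

    def test_reversing_weights_reverses_order(self):
        edges = {(0, 1): 5, (0, 2): 3, (1, 2): 1}
        fwd = build_filtration(net_from_edges(3, edges))
        rev = build_filtration(net_from_edges(3, {e: 6 - w for e, w in edges.items()}))
        assert rev.edges == fwd.edges[::-1]

    def test_strict_mode_rejects_duplicates(self):
        net = net_from_edges(3, {(0, 1): 2, (0, 2): 2, (1, 2): 1})
        with pytest.raises(ValueError, match="duplicate"):
            build_filtration(net, tiebreak="strict")


class TestDiagram:
    def test_square_fixture_single_dim1_point(self, square):
        net, gt = square
        d = persistent_homology(build_filtration(net))
        pts = d.positive(1)
        assert len(pts) == 1
        assert pts[0].rho_birth == pytest.approx(4 / 6)
        assert pts[0].rho_death == pytest.approx(5 / 6)
        assert pts[0].lifetime == pytest.approx(1 / 6)
        assert pts[0].pi == pytest.approx(5 / 4)
        assert d.positive(2) == []

    def test_octahedron_fixture_single_dim2_point(self, octahedron):
        net, gt = octahedron
        d = persistent_homology(build_filtration(net))
        pts = d.positive(2)
        assert len(pts) == 1
        assert pts[0].rho_birth == pytest.approx(12 / 15)
        assert pts[0].rho_death == pytest.approx(13 / 15)
        # no 1-cavity survives the final network
        assert all(p.death_step is not None for p in d.positive(1))

    def test_complete_graph_contractible(self):
        rng = np.random.default_rng(0)
        for n in (5, 7, 10):
            w = np.triu(rng.random((n, n)) + 0.1, 1)
            d = persistent_homology(build_filtration(cc.WeightedNetwork(w + w.T)))
            assert all(p.death_step is not None for p in d.points)

    def test_incomplete_network_reports_infinite_bars(self, square):
        net, _ = square
        w = net.weights.copy()
        w[0, 2] = w[2, 0] = 0  # drop the chord: the cavity is never filled
        d = persistent_homology(build_filtration(cc.WeightedNetwork(w)))
        (pt,) = d.positive(1)
        assert pt.death_step is None and math.isinf(pt.rho_death)

    def test_stability_under_tiny_order_preserving_noise(self):
        rng = np.random.default_rng(1)
        net = random_er_network(9, 0.5, rng)
        base = persistent_homology(build_filtration(net))
        jitter = rng.uniform(-1e-7, 1e-7, size=net.weights.shape)
        jitter = np.triu(jitter, 1) * (np.triu(net.weights, 1) > 0)
        perturbed = cc.WeightedNetwork(net.weights + jitter + jitter.T)
        other = persistent_homology(build_filtration(perturbed))
        key = lambda d: sorted(
            (p.dimension, p.birth_step, p.death_step) for p in d.points
        )
        assert key(base) == key(other)

    @given(st.permutations(range(8)))
    def test_diagram_invariant_under_node_relabeling(self, perm):
        rng = np.random.default_rng(13)
        net = random_er_network(8, 0.6, rng)
        permuted = cc.WeightedNetwork(net.weights[np.ix_(list(perm), list(perm))])
        key = lambda d: sorted(
            (p.dimension, p.birth_step, p.death_step) for p in d.points
        )
        assert key(persistent_homology(build_filtration(net))) == key(
            persistent_homology(build_filtration(permuted))
        )


class TestBettiOracle:
    def test_square_complete_has_beta1_one(self, square):
        net, _ = square
        f = build_filtration(net)
        assert betti_numbers_at(f, 4) == [1, 1, 0]

    def test_connected_final_step_beta0_one(self):
        rng = np.random.default_rng(2)
        _, geo = cc.random_geometric_network(8, seed=3)
        f = build_filtration(geo)
        assert betti_numbers_at(f, f.n_steps)[0] == 1

    def test_empty_step(self):
        net = net_from_edges(5, {(0, 1): 1})
        f = build_filtration(net)
        assert betti_numbers_at(f, 0) == [5, 0, 0]

    def test_step_out_of_range(self, square):
        net, _ = square
        f = build_filtration(net)
        with pytest.raises(ValueError, match="out of range"):
            betti_numbers_at(f, f.n_steps + 1)

    def test_betti_curves_match_pointwise_oracle(self, octahedron):
        net, _ = octahedron
        f = build_filtration(net)
        curves = cc.betti_curves(f)
        for _, row in curves.iterrows():
            b = betti_numbers_at(f, int(row["step"]))
            assert [row["beta0"], row["beta1"], row["beta2"]] == b


class TestDiagramOracleConsistency:
    @pytest.mark.parametrize("seed", range(10))
    def test_alive_counts_equal_betti(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(5, 12))
        net = random_er_network(n, rng.uniform(0.3, 0.8), rng)
        f = build_filtration(net)
        d = persistent_homology(f)
        for s in range(f.n_steps + 1):
            b = betti_numbers_at(f, s)
            assert d.alive(1, s) == b[1]
            assert d.alive(2, s) == b[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_euler_identity_every_step(self, seed):
        rng = np.random.default_rng(300 + seed)
        net = random_er_network(int(rng.integers(5, 11)), 0.5, rng)
        f = build_filtration(net)
        assert all(
            euler_characteristic_check(f, s) for s in range(f.n_steps + 1)
        )
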