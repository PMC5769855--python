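import numpy as np
import pytest

import cliquecav as cc
from cliquecav.cycles import (
    CycleRepresentative,
    FlagComplexSlice,
    RepresentativeCapError,
    cycle_is_trivial,
    cycles_equivalent,
    minimal_1cycles,
    minimal_2cycles,
)
from cliquecav.persistence import build_filtration, persistent_homology

from conftest import net_from_edges


def _the_point(net, dim):
    f = build_filtration(net)
    pts = persistent_homology(f).positive(dim)
    assert len(pts) == 1
    return f, pts[0]


class TestEquivalence:
    def test_square_equivalent_to_chord_detour(self, square):
        net, _ = square
        f = build_filtration(net)
        cx = FlagComplexSlice(f, 5, max_dim=2)  # all five edges present
        sq = CycleRepresentative(1, frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}), 5)
        detour = CycleRepresentative(1, frozenset({(0, 1), (1, 2), (0, 2)}), 5)
        assert cycles_equivalent(sq, detour, cx)

    def test_triangle_with_its_3clique_is_trivial(self):
        net = net_from_edges(3, {(0, 1): 3, (1, 2): 2, (0, 2): 1})
        f = build_filtration(net)
        cx = FlagComplexSlice(f, 3, max_dim=2)
        tri = CycleRepresentative(1, frozenset({(0, 1), (1, 2), (0, 2)}), 3)
        assert cycle_is_trivial(tri, cx)

    def test_square_nontrivial_without_chord(self, square):
        net, _ = square
        f = build_filtration(net)
        cx = FlagComplexSlice(f, 4, max_dim=2)  # chord not yet added
        sq = CycleRepresentative(1, frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}), 4)
        empty = CycleRepresentative(1, frozenset(), 4)
        assert not cycles_equivalent(sq, empty, cx)
        assert not cycle_is_trivial(sq, cx)

    def test_tetrahedron_shell_bounds_in_its_own_complex(self):
        w = np.ones((4, 4)) - np.eye(4)
        w *= np.array([[0, 6, 5, 4], [6, 0, 3, 2], [5, 3, 0, 1], [4, 2, 1, 0]])
        f = build_filtration(cc.WeightedNetwork(w))
        cx = FlagComplexSlice(f, 6, max_dim=3)
        shell = CycleRepresentative(
            2, frozenset({(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)}), 6
        )
        assert cycle_is_trivial(shell, cx)

    def test_clique_absent_from_slice_rejected(self, square):
        net, _ = square
        f = build_filtration(net)
        cx = FlagComplexSlice(f, 2, max_dim=2)
        sq = CycleRepresentative(1, frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}), 2)
        with pytest.raises(ValueError, match="absent"):
            cycle_is_trivial(sq, cx)


class TestMinimal1Cycles:
    def test_square_unique_four_node_representative(self, square):
        net, _ = square
        f, pt = _the_point(net, 1)
        reps = minimal_1cycles(f, pt)
        assert len(reps) == 1
        assert reps[0].nodes == frozenset({0, 1, 2, 3})
        assert reps[0].is_closed()
        assert tuple(sorted(pt.birth_simplex)) in reps[0].cliques

    def test_planted_pentagon_unique_representative(self):
        edges = {(0, 1): 10, (1, 2): 9, (2, 3): 8, (3, 4): 7, (0, 4): 6, (0, 2): 1}
        net = net_from_edges(5, edges)
        f, pt = _the_point(net, 1)
        reps = minimal_1cycles(f, pt)
        assert len(reps) == 1
        assert reps[0].nodes == frozenset(range(5))

    def test_parallel_inequivalent_paths_both_returned(self):
        # theta graph: birth edge (0,3) closes two non-equivalent 4-cycles
        edges = {
            (0, 1): 10, (1, 2): 9, (2, 3): 8,
            (0, 4): 7, (4, 5): 6, (3, 5): 5,
            (0, 3): 4,
        }
        net = net_from_edges(6, edges)
        f = build_filtration(net)
        d = persistent_homology(f)
        pt = next(p for p in d.positive(1) if set(p.birth_simplex) == {0, 3})
        reps = minimal_1cycles(f, pt)
        assert len(reps) == 2
        assert {r.nodes for r in reps} == {
            frozenset({0, 1, 2, 3}),
            frozenset({0, 4, 5, 3}),
        }
        assert {r.class_id for r in reps} == {0, 1}

    def test_representatives_stable_under_order_preserving_jitter(self, square):
        net, _ = square
        f, pt = _the_point(net, 1)
        jittered = cc.WeightedNetwork(net.weights * 1.0 + (net.weights > 0) * 1e-7)
        f2, pt2 = _the_point(jittered, 1)
        a = {r.cliques for r in minimal_1cycles(f, pt)}
        b = {r.cliques for r in minimal_1cycles(f2, pt2)}
        assert a == b

    def test_all_representatives_verified_nonbounding(self, square):
        net, _ = square
        f, pt = _the_point(net, 1)
        cx = FlagComplexSlice(f, pt.birth_step, max_dim=2)
        for rep in minimal_1cycles(f, pt):
            assert not cycle_is_trivial(rep, cx)


class TestMinimal2Cycles:
    def test_octahedron_six_nodes_eight_triangles(self, octahedron):
        net, _ = octahedron
        f, pt = _the_point(net, 2)
        reps = minimal_2cycles(f, pt)
        assert len(reps) == 1
        assert reps[0].nodes == frozenset(range(6))
        assert len(reps[0].cliques) == 8
        assert reps[0].is_closed()

    def test_cap_below_answer_is_an_error(self, octahedron):
        net, _ = octahedron
        f, pt = _the_point(net, 2)
        with pytest.raises(RepresentativeCapError):
            minimal_2cycles(f, pt, node_cap=5)

    def test_wrong_dimension_rejected(self, square):
        net, _ = square
        f, pt = _the_point(net, 1)
        with pytest.raises(ValueError):
            minimal_2cycles(f, pt)
        oct_net, _ = cc.planted_cavity_network(cc.octahedron_cavity_spec())
        f2, pt2 = _the_point(oct_net, 2)
        with pytest.raises(ValueError):
            minimal_1cycles(f2, pt2)
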