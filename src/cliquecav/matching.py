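"""Cross-scan cavity similarity heuristic.

Given a reference cavity — a persistence class with its set of minimal
representatives l_0..l_m and their node sets N_0..N_m — and a target scan,
two questions are asked:

1. *Nodes connected in a cycle*: does the subgraph induced on some N_i,
   filtered by its own edge weights, carry precisely one non-trivial class
   of the reference dimension at some density?
2. *Similar topological cavity*: scanning the target's persistence classes
   in order of increasing birth density, restricted to those whose birth
   clique touches some N_i, does one of them match by
   (a) a minimal generator equal or Z2-equivalent to a reference
   representative at its birth density,
   (b) a generator at the birth density using all but at most one node of
   some N_i, at most two extra nodes, with the shared nodes in the
   reference's cyclic order, or
   (c) condition (a) or (b) holding at some density within the class's
   lifetime?

A class whose birth clique avoids every reference node is never examined;
this known false-negative mode of the heuristic is deliberate, documented
behaviour.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cycles import (
    CycleRepresentative,
    FlagComplexSlice,
    cycles_equivalent,
    minimal_1cycles,
    minimal_2cycles,
)
from .network import WeightedNetwork
from .persistence import (
    Diagram,
    Filtration,
    PersistencePoint,
    betti_numbers_at,
    build_filtration,
    persistent_homology,
)

__all__ = ["Rule1Result", "MatchResult", "rule1_nodes_form_cycle", "rule2_similar_cavity", "match_scan"]


@dataclasses.dataclass
class Rule1Result:
    """Outcome of the induced-subgraph cycle test for one node set N_i."""

    node_set: frozenset[int]
    found: bool
    step: int | None = None
    density: float | None = None  # on the subgraph's own density scale
    edges_at_step: list[tuple[int, int]] | None = None


@dataclasses.dataclass
class MatchResult:
    """Outcome of the similarity heuristic on one scan."""

    scan_id: str
    rule1: list[Rule1Result]
    rule2_found: bool
    subrule: str | None = None  # 'a', 'b' or 'c'
    density: float | None = None
    point: PersistencePoint | None = None

    @property
    def rule1_any(self) -> bool:
        return any(r.found for r in self.rule1)


def rule1_nodes_form_cycle(
    node_sets: list[frozenset[int]],
    scan: WeightedNetwork,
    dimension: int = 1,
) -> list[Rule1Result]:
    """For each N_i: first density where the induced subgraph carries
    precisely one non-trivial class of the given dimension.

    The induced subgraph is filtered by its own edge weights and densities
    are on the subgraph's own scale.  Node sets smaller than 3 are an
    error (no cycle can form).
    """
    results = []
    for nodes in node_sets:
        nodes = frozenset(nodes)
        if len(nodes) < 3:
            raise ValueError(f"node set {sorted(nodes)} too small to carry a cycle")
        idx = sorted(nodes)
        sub = scan.weights[np.ix_(idx, idx)]
        subnet = WeightedNetwork(sub, [scan.node_ids[v] for v in idx])
        filt = build_filtration(subnet)
        hit = None
        for step in range(1, filt.n_steps + 1):
            betti = betti_numbers_at(filt, step, max_dim=dimension)
            if betti[dimension] == 1:
                hit = step
                break
        if hit is None:
            results.append(Rule1Result(nodes, False))
        else:
            edges = [(idx[a], idx[b]) for a, b in filt.edges[:hit]]
            results.append(
                Rule1Result(nodes, True, hit, filt.density(hit), edges)
            )
    return results


def _cyclic_variants(seq: list[int]) -> set[tuple[int, ...]]:
    out = set()
    for s in (seq, seq[::-1]):
        for r in range(len(s)):
            out.add(tuple(s[r:] + s[:r]))
    return out


def _order_preserved(ref_order: list[int], gen_order: list[int], shared: set[int]) -> bool:
    """Shared nodes appear in the same cyclic order (rotation/reflection)."""
    ref_seq = [v for v in ref_order if v in shared]
    gen_seq = [v for v in gen_order if v in shared]
    if len(ref_seq) != len(gen_seq):
        return False
    if len(ref_seq) <= 2:
        return True
    return tuple(gen_seq) in _cyclic_variants(ref_seq)


def _test_2a(
    generators: list[CycleRepresentative],
    reference: list[CycleRepresentative],
    cx: FlagComplexSlice,
) -> bool:
    for gen in generators:
        for ref in reference:
            if gen.cliques == ref.cliques:
                return True
            if all(cx.contains(c) for c in ref.cliques) and cycles_equivalent(gen, ref, cx):
                return True
    return False


def _test_2b(
    generators: list[CycleRepresentative],
    reference: list[CycleRepresentative],
) -> bool:
    for gen in generators:
        gnodes = set(gen.nodes)
        for ref in reference:
            rnodes = set(ref.nodes)
            shared = gnodes & rnodes
            extras = gnodes - rnodes
            if len(shared) < len(rnodes) - 1 or len(extras) > 2:
                continue
            if gen.dimension != 1:
                return True  # cyclic order is vacuous beyond polygons
            try:
                ref_order = ref.cyclic_order()
                gen_order = gen.cyclic_order()
            except ValueError:
                continue
            if _order_preserved(ref_order, gen_order, shared):
                return True
    return False


def _generators_at(
    filt: Filtration, point: PersistencePoint, step: int, birth_gens: list[CycleRepresentative]
) -> list[CycleRepresentative]:
    """Minimal generators of the class at a step within its lifetime.

    BFS candidates are filtered to those still Z2-equivalent, at the
    requested step, to a birth representative of the class (which remains
    a member cycle of the class while it is alive).
    """
    if step == point.birth_step:
        return birth_gens
    cx = FlagComplexSlice(filt, step, max_dim=point.dimension + 1)
    cands = minimal_1cycles(filt, point, at_step=step)
    return [g for g in cands if any(cycles_equivalent(g, b, cx) for b in birth_gens)]


def rule2_similar_cavity(
    reference: list[CycleRepresentative],
    scan_filt: Filtration,
    scan_diagram: Diagram | None = None,
    node_cap: int = 12,
) -> tuple[bool, str | None, float | None, PersistencePoint | None]:
    """Find the first scan class matching the reference cavity (rules 2a-2c).

    Returns (found, subrule, density, point).  Candidate classes are those
    of the reference dimension whose birth clique contains a reference
    node, visited in order of increasing birth density.
    """
    if not reference:
        raise ValueError("need at least one reference representative")
    dim = reference[0].dimension
    ref_nodes = set().union(*(r.nodes for r in reference))
    if scan_diagram is None:
        scan_diagram = persistent_homology(scan_filt, max_dim=dim)
    candidates = sorted(
        (
            p
            for p in scan_diagram.positive(dim)
            if set(p.birth_simplex) & ref_nodes
        ),
        key=lambda p: p.rho_birth,
    )
    for point in candidates:
        if dim == 1:
            birth_gens = minimal_1cycles(scan_filt, point)
        else:
            birth_gens = minimal_2cycles(scan_filt, point, node_cap=node_cap)
        cx_birth = FlagComplexSlice(scan_filt, point.birth_step, max_dim=dim + 1)
        if _test_2a(birth_gens, reference, cx_birth):
            return True, "a", point.rho_birth, point
        if _test_2b(birth_gens, reference):
            return True, "b", point.rho_birth, point
        if dim == 1:
            # 2c: re-test within the lifetime wherever the minimal
            # representatives change
            death = (
                point.death_step
                if point.death_step is not None
                else scan_filt.n_steps + 1
            )
            prev = {g.cliques for g in birth_gens}
            for step in range(point.birth_step + 1, death):
                gens = _generators_at(scan_filt, point, step, birth_gens)
                if {g.cliques for g in gens} == prev:
                    continue
                prev = {g.cliques for g in gens}
                cx = FlagComplexSlice(scan_filt, step, max_dim=dim + 1)
                if _test_2a(gens, reference, cx) or _test_2b(gens, reference):
                    return True, "c", scan_filt.density(step), point
    return False, None, None, None


def match_scan(
    reference: list[CycleRepresentative],
    scan: WeightedNetwork,
    scan_id: str = "",
    node_cap: int = 12,
) -> MatchResult:
    """Run both similarity rules against one scan."""
    node_sets = sorted({r.nodes for r in reference}, key=lambda s: tuple(sorted(s)))
    dim = reference[0].dimension
    rule1 = rule1_nodes_form_cycle(list(node_sets), scan, dimension=dim)
    filt = build_filtration(scan)
    found, subrule, density, point = rule2_similar_cavity(reference, filt)
    return MatchResult(scan_id, rule1, found, subrule, density, point)
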