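"""Minimal cycle representatives and Z2 equivalence of cycles.

A k-cycle is a collection of (k+1)-cliques whose k-faces each appear an
even number of times; two cycles are equivalent when they differ by the
boundary of a collection of (k+2)-cliques, and a cycle equivalent to the
empty cycle is trivial (bounding).  A persistence class's minimal
representatives are the cycles in its class at the birth density with the
fewest nodes.  For dimension 1 these are found by breadth-first search:
threshold at the density immediately preceding the birth, take every
minimum-length path between the birth edge's endpoints, and close each
with the birth edge.  For dimension 2 an exhaustive search over connected
node subsets containing the birth triangle is used, capped at ``node_cap``
nodes (hitting the cap is an error, never a silent truncation).
"""

from __future__ import annotations

import dataclasses
import itertools

import networkx as nx

from . import _gf2
from .persistence import Filtration, PersistencePoint, _cliques_at, _clique_stamp

__all__ = [
    "CycleRepresentative",
    "FlagComplexSlice",
    "RepresentativeCapError",
    "cycles_equivalent",
    "cycle_is_trivial",
    "minimal_1cycles",
    "minimal_2cycles",
    "minimal_cycles",
]


class RepresentativeCapError(RuntimeError):
    """A search cap was hit before the result could be certified complete."""


@dataclasses.dataclass(frozen=True)
class CycleRepresentative:
    """A closed non-bounding k-cycle: a set of (k+1)-cliques.

    ``class_id`` groups representatives of one persistence point into Z2
    equivalence classes (0, 1, ... in discovery order).
    """

    dimension: int
    cliques: frozenset[tuple[int, ...]]
    birth_step: int
    class_id: int = 0

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(v for c in self.cliques for v in c)

    def is_closed(self) -> bool:
        count: dict[tuple[int, ...], int] = {}
        for c in self.cliques:
            for f in itertools.combinations(c, self.dimension):
                count[f] = count.get(f, 0) + 1
        return all(v % 2 == 0 for v in count.values())

    def cyclic_order(self) -> list[int]:
        """Node order around a 1-cycle that is a simple polygon."""
        if self.dimension != 1:
            raise ValueError("cyclic order is defined for 1-cycles only")
        adj: dict[int, list[int]] = {}
        for a, b in self.cliques:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        if any(len(nbrs) != 2 for nbrs in adj.values()):
            raise ValueError("not a simple polygon: some node degree != 2")
        start = min(adj)
        order = [start, min(adj[start])]
        while len(order) < len(adj):
            prev, cur = order[-2], order[-1]
            nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
            order.append(nxt)
        return order


class FlagComplexSlice:
    """The flag complex of one filtration step, up to a maximum dimension.

    Holds all cliques with <= max_dim+2 nodes present at the step, each
    implicitly stamped by its latest edge.
    """

    def __init__(self, filt: Filtration, step: int, max_dim: int = 2):
        self.filtration = filt
        self.step = step
        self.max_dim = max_dim
        adj = filt.adjacency_at(step)
        self._by_size = _cliques_at(adj, max_dim + 2)

    def cliques(self, size: int) -> list[tuple[int, ...]]:
        return self._by_size.get(size, [])

    def contains(self, clique: tuple[int, ...]) -> bool:
        return tuple(sorted(clique)) in set(self._by_size.get(len(clique), []))

    def boundary_image_columns(self, dimension: int) -> tuple[list[int], dict]:
        """Columns of the (dimension+1)-boundary map over the slice's cliques.

        Returns (columns, face_index) where rows are indexed by the
        slice's (dimension+1)-cliques.
        """
        faces = self.cliques(dimension + 1)
        cofaces = self.cliques(dimension + 2)
        face_index = {f: i for i, f in enumerate(faces)}
        cols = []
        for c in cofaces:
            col = 0
            for f in itertools.combinations(c, dimension + 1):
                col |= 1 << face_index[f]
            cols.append(col)
        return cols, face_index


def _cycle_vector(z: CycleRepresentative, face_index: dict) -> int:
    vec = 0
    for c in z.cliques:
        key = tuple(sorted(c))
        if key not in face_index:
            raise ValueError(f"cycle clique {key} absent from the slice")
        vec |= 1 << face_index[key]
    return vec


def cycles_equivalent(
    z1: CycleRepresentative, z2: CycleRepresentative, cx: FlagComplexSlice
) -> bool:
    """True iff z1 + z2 (Z2 symmetric difference) bounds in the slice."""
    if z1.dimension != z2.dimension:
        raise ValueError("cycles have different dimensions")
    cols, face_index = cx.boundary_image_columns(z1.dimension)
    target = _cycle_vector(z1, face_index) ^ _cycle_vector(z2, face_index)
    return _gf2.in_span(cols, target)


def cycle_is_trivial(z: CycleRepresentative, cx: FlagComplexSlice) -> bool:
    """Equivalence with the empty cycle: the cycle bounds in the slice."""
    cols, face_index = cx.boundary_image_columns(z.dimension)
    return _gf2.in_span(cols, _cycle_vector(z, face_index))


def _assign_class_ids(
    reps: list[CycleRepresentative], cx: FlagComplexSlice
) -> list[CycleRepresentative]:
    classes: list[CycleRepresentative] = []
    out = []
    for rep in reps:
        cid = None
        for k, other in enumerate(classes):
            if cycles_equivalent(rep, other, cx):
                cid = k
                break
        if cid is None:
            cid = len(classes)
            classes.append(rep)
        out.append(dataclasses.replace(rep, class_id=cid))
    return out


def minimal_1cycles(
    filt: Filtration,
    point: PersistencePoint,
    cap: int = 100,
    at_step: int | None = None,
) -> list[CycleRepresentative]:
    """All minimal representatives of a dim-1 class at its birth density.

    The graph is thresholded at the step immediately preceding the birth
    edge; every minimum-length path between the birth edge's endpoints,
    closed with the birth edge, is a candidate.  Candidates that bound at
    the evaluation step are discarded; survivors are tagged with Z2
    equivalence-class ids.  ``at_step`` evaluates the same construction at
    a later density (used when tracking a class through its lifetime).
    """
    if point.dimension != 1:
        raise ValueError("point must be a dimension-1 class")
    step = point.birth_step if at_step is None else at_step
    u, v = point.birth_simplex
    g = nx.Graph()
    g.add_nodes_from(range(filt.n_nodes))
    for i, j in filt.edges[:step]:
        g.add_edge(i, j)
    if g.has_edge(u, v):
        g.remove_edge(u, v)
    if not nx.has_path(g, u, v):
        raise RuntimeError(
            "birth-edge endpoints disconnected before the birth step; "
            "inconsistent filtration/point"
        )
    paths = []
    for p in nx.all_shortest_paths(g, u, v):
        paths.append(p)
        if len(paths) > cap:
            raise RepresentativeCapError(
                f"more than {cap} minimum-length paths for birth edge ({u},{v})"
            )
    cx = FlagComplexSlice(filt, step, max_dim=1 + 1)
    reps = []
    for p in paths:
        edges = {tuple(sorted((a, b))) for a, b in zip(p, p[1:])}
        edges.add(tuple(sorted((u, v))))
        rep = CycleRepresentative(1, frozenset(edges), step)
        if not cycle_is_trivial(rep, cx):
            reps.append(rep)
    if not reps:
        raise RuntimeError(
            "all candidate minimal cycles bound at the birth step; "
            "inconsistent filtration/point"
        )
    return _assign_class_ids(reps, cx)


def _connected_subsets(
    adj: list[set[int]], seed_nodes: frozenset[int], size: int
) -> list[frozenset[int]]:
    """Connected node sets of a given size containing all seed nodes."""
    out: set[frozenset[int]] = set()
    frontier = {seed_nodes}
    while frontier:
        nxt = set()
        for s in frontier:
            if len(s) == size:
                out.add(s)
                continue
            boundary = set().union(*(adj[v] for v in s)) - s
            for v in boundary:
                nxt.add(s | {v})
        frontier = nxt
    return sorted(out, key=lambda s: tuple(sorted(s)))


def minimal_2cycles(
    filt: Filtration,
    point: PersistencePoint,
    node_cap: int = 12,
    cap: int = 100,
) -> list[CycleRepresentative]:
    """All minimum-node closed non-bounding 2-cycles through the birth triangle.

    Exhaustive search over connected node subsets containing the birth
    triangle, by increasing size: for each subset, the Z2 linear system
    "closed 2-chain supported on the subset's triangles, containing the
    birth triangle" is solved and every solution whose node support is the
    whole subset is kept if it does not bound in the full slice.  Reaching
    ``node_cap`` without a representative raises — no silent truncation.
    """
    if point.dimension != 2:
        raise ValueError("point must be a dimension-2 class")
    step = point.birth_step
    cx = FlagComplexSlice(filt, step, max_dim=3)
    birth = tuple(sorted(point.birth_simplex))
    adj = filt.adjacency_at(step)
    bound_cols, face_index = cx.boundary_image_columns(2)
    triangles = cx.cliques(3)
    seed = frozenset(birth)
    for size in range(3, node_cap + 1):
        found: list[CycleRepresentative] = []
        for subset in _connected_subsets(adj, seed, size):
            tris = [t for t in triangles if set(t) <= subset]
            if birth not in tris:
                continue
            # solve d2 x = 0 with x_birth = 1 over the subset's triangles
            tri_index = {t: i for i, t in enumerate(tris)}
            particular, kernel = _solve_cycle_system(tris, tri_index[birth])
            if particular is None:
                continue
            if len(kernel) > 20:
                raise RepresentativeCapError(
                    f"kernel dimension {len(kernel)} too large to enumerate"
                )
            for combo_bits in range(1 << len(kernel)):
                sol = particular
                for b in range(len(kernel)):
                    if combo_bits >> b & 1:
                        sol ^= kernel[b]
                chain = frozenset(
                    tris[i] for i in range(len(tris)) if sol >> i & 1
                )
                if not chain:
                    continue
                nodes = frozenset(v for t in chain for v in t)
                if nodes != subset:
                    continue  # smaller supports were handled at their own size
                rep = CycleRepresentative(2, chain, step)
                target = 0
                for t in chain:
                    target |= 1 << face_index[t]
                if not _gf2.in_span(bound_cols, target):
                    found.append(rep)
                    if len(found) > cap:
                        raise RepresentativeCapError(
                            f"more than {cap} minimal 2-cycle representatives"
                        )
        if found:
            return _assign_class_ids(found, cx)
    raise RepresentativeCapError(
        f"no closed non-bounding 2-cycle found within node_cap={node_cap}; "
        "raise the cap to certify the search"
    )


def _solve_cycle_system(
    tris: list[tuple[int, ...]], birth_idx: int
) -> tuple[int | None, list[int]]:
    """Solve: chain x over the triangles, boundary zero, x_birth = 1.

    Rows are the edges of the triangles plus one constraint row forcing
    the birth triangle's coefficient to one.
    """
    edges = sorted({e for t in tris for e in itertools.combinations(t, 2)})
    edge_index = {e: i for i, e in enumerate(edges)}
    constraint_row = len(edges)
    cols = []
    for i, t in enumerate(tris):
        col = 0
        for e in itertools.combinations(t, 2):
            col |= 1 << edge_index[e]
        if i == birth_idx:
            col |= 1 << constraint_row
        cols.append(col)
    target = 1 << constraint_row
    return _gf2.solve_affine(cols, target)


def minimal_cycles(
    filt: Filtration, point: PersistencePoint, node_cap: int = 12, cap: int = 100
) -> list[CycleRepresentative]:
    """Dispatch to the dimension-appropriate minimal-representative search."""
    if point.dimension == 1:
        return minimal_1cycles(filt, point, cap=cap)
    if point.dimension == 2:
        return minimal_2cycles(filt, point, node_cap=node_cap, cap=cap)
    raise ValueError(f"no generator search for dimension {point.dimension}")
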