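"""Weight-rank clique filtration and Z2 persistent homology (dims 1-2).

The filtration starts from the empty graph on all nodes and adds edges one
at a time in order of decreasing weight; each graph in the sequence is
indexed by its edge density rho = (#edges)/(n(n-1)/2).  Homology is taken
of the flag (clique) complex of each graph with Z2 coefficients: a
k-dimensional topological cavity is a non-trivial equivalence class of
k-cycles, born at the density where the class first appears and dying when
the enclosed void is triangulated by higher cliques.

Two independent computations are provided:

* :func:`persistent_homology` — the persistence diagram via standard
  boundary-matrix column reduction (birth/death densities, birth simplex,
  lifetime and death-to-birth ratio pi per cavity);
* :func:`betti_numbers_at` / :func:`betti_curves` — Betti numbers at any
  filtration step from boundary-matrix ranks, used as a cross-check oracle.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable

import numpy as np
import pandas as pd

from . import _gf2
from .network import WeightedNetwork

__all__ = [
    "Filtration",
    "PersistencePoint",
    "Diagram",
    "build_filtration",
    "persistent_homology",
    "betti_numbers_at",
    "betti_curves",
    "euler_characteristic_check",
]


@dataclasses.dataclass
class Filtration:
    """Edge sequence in strictly decreasing weight order.

    Step s (1-based) is the binary graph holding the first s edges; step 0
    is the empty graph on all nodes.  Densities use the all-pairs
    denominator n(n-1)/2, so an incomplete network never reaches rho = 1.
    """

    n_nodes: int
    edges: list[tuple[int, int]]
    weights: list[float]
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if any(w2 > w1 for w1, w2 in zip(self.weights, self.weights[1:])):
            raise ValueError("filtration weights must be non-increasing")

    @property
    def n_steps(self) -> int:
        return len(self.edges)

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def density(self, step: int) -> float:
        return step / self.n_pairs

    def edge_steps(self) -> dict[tuple[int, int], int]:
        """Map each (i<j) edge to its 1-based arrival step."""
        return {e: s + 1 for s, e in enumerate(self.edges)}

    def adjacency_at(self, step: int) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges[:step]:
            adj[i].add(j)
            adj[j].add(i)
        return adj


def build_filtration(net: WeightedNetwork, tiebreak: str = "lex") -> Filtration:
    """Order the network's edges by strictly decreasing weight.

    Duplicate weights are broken by lexicographic node-pair order
    (``tiebreak='lex'``, the deterministic default) or rejected
    (``tiebreak='strict'``); run :func:`~cliquecav.network.add_tiebreak_noise`
    first to reproduce the randomized-noise mode.
    """
    ranked = sorted(
        ((i, j, w) for i, j, w in net.edges()),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    ws = [w for _, _, w in ranked]
    if tiebreak == "strict" and len(set(ws)) != len(ws):
        raise ValueError("duplicate edge weights; perturb weights or use tiebreak='lex'")
    return Filtration(
        net.n_nodes, [(i, j) for i, j, _ in ranked], list(ws), list(net.node_ids)
    )


# ---------------------------------------------------------------------------
# clique (flag-complex) machinery


def _cliques_at(adj: list[set[int]], max_size: int) -> dict[int, list[tuple[int, ...]]]:
    """All cliques of the graph given by ``adj``, grouped by node count.

    Grown incrementally: a (c+1)-clique is a c-clique plus a node adjacent
    to all of its members and larger than the maximum (canonical order).
    """
    n = len(adj)
    out: dict[int, list[tuple[int, ...]]] = {1: [(v,) for v in range(n)]}
    for size in range(2, max_size + 1):
        prev = out.get(size - 1, [])
        cur: list[tuple[int, ...]] = []
        for c in prev:
            cands = set.intersection(*(adj[v] for v in c)) if size > 2 else adj[c[0]]
            last = c[-1]
            for v in cands:
                if v > last:
                    cur.append(c + (v,))
        if not cur:
            out[size] = []
            break
        out[size] = cur
    for size in range(2, max_size + 1):
        out.setdefault(size, [])
    return out


def _clique_stamp(clique: tuple[int, ...], steps: dict[tuple[int, int], int]) -> int:
    """Filtration step at which a clique completes (max over its edges)."""
    if len(clique) == 1:
        return 0
    return max(steps[(a, b)] for a, b in itertools.combinations(clique, 2))


# ---------------------------------------------------------------------------
# persistence diagram


@dataclasses.dataclass
class PersistencePoint:
    """One topological cavity: dimension, birth/death densities, birth clique.

    ``death_step`` is None for classes never filled (the void persists in
    the final network); their density, lifetime and pi are infinite.
    ``birth_simplex`` is the (dim+1)-clique whose arrival creates the class
    — for dimension 1 this is the birth edge.
    """

    dimension: int
    birth_step: int
    death_step: int | None
    rho_birth: float
    rho_death: float
    birth_simplex: tuple[int, ...]

    @property
    def lifetime(self) -> float:
        return self.rho_death - self.rho_birth

    @property
    def pi(self) -> float:
        """Death-to-birth ratio rho_death / rho_birth."""
        return self.rho_death / self.rho_birth


@dataclasses.dataclass
class Diagram:
    """Persistence diagram: the cavities of one filtration."""

    points: list[PersistencePoint]
    filtration: Filtration

    def positive(self, dimension: int | None = None) -> list[PersistencePoint]:
        """Points with strictly positive lifetime (the plotted diagram)."""
        return [
            p
            for p in self.points
            if p.lifetime > 0 and (dimension is None or p.dimension == dimension)
        ]

    def alive(self, dimension: int, step: int) -> int:
        """Number of classes with birth_step <= step < death_step."""
        return sum(
            1
            for p in self.points
            if p.dimension == dimension
            and p.birth_step <= step
            and (p.death_step is None or step < p.death_step)
        )

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.filtration.node_ids or [
            str(i) for i in range(self.filtration.n_nodes)
        ]
        rows = []
        for p in self.points:
            rows.append(
                {
                    "dim": p.dimension,
                    "rho_birth": p.rho_birth,
                    "rho_death": p.rho_death,
                    "lifetime": p.lifetime,
                    "pi": p.pi,
                    "birth_simplex": " ".join(ids[v] for v in p.birth_simplex),
                }
            )
        return pd.DataFrame(
            rows, columns=["dim", "rho_birth", "rho_death", "lifetime", "pi", "birth_simplex"]
        )


def persistent_homology(
    filt: Filtration, max_dim: int = 2, include_zero: bool = True
) -> Diagram:
    """Persistence pairs of the flag-complex filtration over Z2.

    Cliques are stamped with the step of their latest edge; the boundary
    matrix, ordered by (stamp, dimension, node tuple), is reduced by
    standard column addition.  Classes never filled get infinite death.
    Zero-lifetime pairs (a clique and its killer arriving at the same edge
    step) are retained unless ``include_zero=False``; they carry no
    topological signal and are excluded from any density interval.
    """
    steps = filt.edge_steps()
    adj = filt.adjacency_at(filt.n_steps)
    by_size = _cliques_at(adj, max_dim + 2)
    simplices: list[tuple[int, int, tuple[int, ...]]] = []  # (stamp, dim, nodes)
    for size, cliques in by_size.items():
        dim = size - 1
        for c in cliques:
            simplices.append((_clique_stamp(c, steps), dim, c))
    simplices.sort()
    index = {s[2]: k for k, s in enumerate(simplices)}

    pivots: dict[int, int] = {}  # low row -> reduced column bitmask
    pivot_col: dict[int, int] = {}  # low row -> column index (the killer's victim)
    births: set[int] = set()
    pairs: list[tuple[int, int]] = []  # (birth simplex idx, death simplex idx)
    for j, (stamp, dim, nodes) in enumerate(simplices):
        if dim == 0:
            continue
        col = 0
        for facet in itertools.combinations(nodes, dim):
            col |= 1 << index[facet]
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                break
        if col:
            low = col.bit_length() - 1
            pivots[low] = col
            pivot_col[low] = j
            pairs.append((low, j))
        else:
            births.add(j)

    paired_births = {i for i, _ in pairs}
    points: list[PersistencePoint] = []
    npairs = filt.n_pairs
    for i, j in pairs:
        stamp_b, dim_b, nodes_b = simplices[i]
        stamp_d, _, _ = simplices[j]
        if dim_b < 1 or dim_b > max_dim:
            continue
        if stamp_b == stamp_d and not include_zero:
            continue
        points.append(
            PersistencePoint(
                dim_b, stamp_b, stamp_d, stamp_b / npairs, stamp_d / npairs, nodes_b
            )
        )
    for j in sorted(births - paired_births):
        stamp, dim, nodes = simplices[j]
        if dim < 1 or dim > max_dim:
            continue
        points.append(
            PersistencePoint(dim, stamp, None, stamp / npairs, math.inf, nodes)
        )
    points.sort(key=lambda p: (p.dimension, p.birth_step, p.rho_death))
    return Diagram(points, filt)


# ---------------------------------------------------------------------------
# rank oracle: Betti numbers from boundary-matrix ranks


def _boundary_columns(
    faces: list[tuple[int, ...]], cofaces: list[tuple[int, ...]]
) -> list[int]:
    idx = {f: k for k, f in enumerate(faces)}
    cols = []
    for c in cofaces:
        col = 0
        for facet in itertools.combinations(c, len(c) - 1):
            col |= 1 << idx[facet]
        cols.append(col)
    return cols


def betti_numbers_at(
    filt: Filtration, step: int, max_dim: int = 2, truncated_top: bool = False
) -> list[int]:
    """Betti numbers beta_0..beta_max_dim of the flag complex at one step.

    Computed directly from GF(2) ranks of the boundary matrices
    (beta_k = n_k - rank d_k - rank d_{k+1}), independently of the
    reduction used for the persistence diagram.  With ``truncated_top``
    the list is extended by beta_{max_dim+1} of the complex truncated at
    dimension max_dim+1 (no higher boundary), as needed for the Euler
    identity of the truncated complex.
    """
    if not 0 <= step <= filt.n_steps:
        raise ValueError(f"step {step} out of range 0..{filt.n_steps}")
    adj = filt.adjacency_at(step)
    by_size = _cliques_at(adj, max_dim + 2)
    counts = {size - 1: len(by_size[size]) for size in by_size}
    ranks: dict[int, int] = {}
    for dim in range(1, max_dim + 2):
        faces = by_size[dim]
        cofaces = by_size[dim + 1]
        ranks[dim] = _gf2.rank(_boundary_columns(faces, cofaces)) if cofaces else 0
    betti = []
    for k in range(max_dim + 1):
        betti.append(counts.get(k, 0) - ranks.get(k, 0) - ranks.get(k + 1, 0))
    if truncated_top:
        k = max_dim + 1
        betti.append(counts.get(k, 0) - ranks.get(k, 0))
    return betti


def betti_curves(
    filt: Filtration, max_dim: int = 2, steps: Iterable[int] | None = None
) -> pd.DataFrame:
    """Betti numbers at every requested step (default: all steps)."""
    if steps is None:
        steps = range(filt.n_steps + 1)
    rows = []
    for s in steps:
        b = betti_numbers_at(filt, s, max_dim)
        rows.append({"step": s, "rho": filt.density(s), **{f"beta{k}": b[k] for k in range(max_dim + 1)}})
    return pd.DataFrame(rows)


def euler_characteristic_check(filt: Filtration, step: int, max_dim: int = 2) -> bool:
    """Alternating clique-count sum equals alternating Betti sum at a step.

    Both sides are evaluated on the complex truncated at dimension
    max_dim+1 so the identity is exact by rank-nullity.
    """
    adj = filt.adjacency_at(step)
    by_size = _cliques_at(adj, max_dim + 2)
    chi_counts = sum((-1) ** (size - 1) * len(by_size[size]) for size in by_size)
    betti = betti_numbers_at(filt, step, max_dim, truncated_top=True)
    chi_betti = sum((-1) ** k * b for k, b in enumerate(betti))
    return chi_counts == chi_betti
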