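"""Synthetic networks with known ground truth.

Four generators cover the study conditions downstream stages need:

* :func:`minimally_wired` — the geometric null model: nodes at given 3D
  positions, every pair linked with weight 1/d(i,j) (inverse Euclidean
  distance), mimicking strict wiring-cost minimisation.
* :func:`random_geometric_network` — i.i.d. uniform points in a box fed
  through the minimally wired construction.
* :func:`planted_cavity_network` — a network whose only k-dimensional
  cavity (k = 1 or 2) is planted with exact, by-construction birth and
  death positions in the edge ordering; weights are assigned by rank
  (descending integers) so ground truth is exact rather than sampled.
* :func:`perturb_scans` — an ensemble of noisy "re-scans" of a template
  (multiplicative log-normal weight jitter plus Bernoulli edge flips).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .network import WeightedNetwork
from .persistence import Filtration, betti_numbers_at

__all__ = [
    "PlantedCavitySpec",
    "PlantedSpecError",
    "minimally_wired",
    "random_geometric_network",
    "planted_cavity_network",
    "square_cavity_spec",
    "octahedron_cavity_spec",
    "perturb_scans",
]


def minimally_wired(
    coords: np.ndarray, node_ids: list[str] | None = None
) -> WeightedNetwork:
    """Complete network with edge weights 1/d(i,j) on given coordinates.

    Coincident points would give infinite weight and are rejected.  The
    caller typically thresholds the result at the empirical edge density.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 points of equal dimension")
    d = pdist(coords)
    if np.any(d == 0):
        raise ValueError("coincident points give infinite weight")
    w = squareform(1.0 / d)
    return WeightedNetwork(w, node_ids)


def random_geometric_network(
    n: int, seed: int | None = None, box: float = 1.0
) -> tuple[np.ndarray, WeightedNetwork]:
    """n i.i.d. uniform points in a cube, minimally wired."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    return coords, minimally_wired(coords)


# ---------------------------------------------------------------------------
# planted cavities


class PlantedSpecError(ValueError):
    """Planted-cavity specification cannot be realised as stated."""


@dataclasses.dataclass
class PlantedCavitySpec:
    """A single planted k-cavity (k = 1 or 2).

    ``shell`` lists the (k+1)-cliques of a closed k-cycle (edges for k=1,
    triangles for k=2); ``fill_edges`` are the edges whose arrival
    triangulates the cavity shut.  ``target_birth_index`` and
    ``target_death_index`` are 1-based positions in the edge ordering at
    which the shell completes and the first fill edge arrives.
    """

    shell: list[tuple[int, ...]]
    n_nodes: int
    target_birth_index: int
    target_death_index: int
    fill_edges: list[tuple[int, int]]

    @property
    def dimension(self) -> int:
        return len(self.shell[0]) - 1

    def shell_edges(self) -> list[tuple[int, int]]:
        seen: dict[tuple[int, int], None] = {}
        for clique in self.shell:
            for a, b in itertools.combinations(sorted(clique), 2):
                seen.setdefault((a, b), None)
        return list(seen)

    def shell_nodes(self) -> set[int]:
        return {v for c in self.shell for v in c}

    def validate(self) -> None:
        sizes = {len(c) for c in self.shell}
        if len(sizes) != 1 or next(iter(sizes)) not in (2, 3):
            raise PlantedSpecError("shell cliques must all be edges or all triangles")
        k = self.dimension
        # closed over Z2: every (k-1)-face appears an even number of times
        face_count: dict[tuple[int, ...], int] = {}
        for c in self.shell:
            for f in itertools.combinations(sorted(c), k):
                face_count[f] = face_count.get(f, 0) + 1
        odd = [f for f, c in face_count.items() if c % 2]
        if odd:
            raise PlantedSpecError(f"shell is not closed: odd faces {odd[:5]}")
        if not self.target_birth_index < self.target_death_index:
            raise PlantedSpecError("target_birth_index must precede target_death_index")
        if self.target_birth_index < len(self.shell_edges()):
            raise PlantedSpecError("birth index smaller than the number of shell edges")
        if max(self.shell_nodes() | {v for e in self.fill_edges for v in e}) >= self.n_nodes:
            raise PlantedSpecError("node index exceeds n_nodes")
        if not self.fill_edges:
            raise PlantedSpecError("need at least one fill edge")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedCavitySpec":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            shell=[tuple(c) for c in raw["shell"]],
            n_nodes=int(raw["n_nodes"]),
            target_birth_index=int(raw["target_birth_index"]),
            target_death_index=int(raw["target_death_index"]),
            fill_edges=[tuple(e) for e in raw["fill_edges"]],
        )


def square_cavity_spec() -> PlantedCavitySpec:
    """4-node square shell killed by one chord: dim-1 cavity at (4/6, 5/6)."""
    return PlantedCavitySpec(
        shell=[(0, 1), (1, 2), (2, 3), (0, 3)],
        n_nodes=4,
        target_birth_index=4,
        target_death_index=5,
        fill_edges=[(0, 2)],
    )


def octahedron_cavity_spec() -> PlantedCavitySpec:
    """Octahedral 2-sphere killed by one antipodal diagonal: dim-2 at (12/15, 13/15).

    The octahedron is K6 minus the perfect matching (0,5), (1,3), (2,4);
    its 8 triangles form the shell.  Adding diagonal (0,5) creates four
    tetrahedra whose boundaries fill the sphere.
    """
    antipodal = {(0, 5), (1, 3), (2, 4)}
    shell = [
        t
        for t in itertools.combinations(range(6), 3)
        if not any(p in antipodal for p in itertools.combinations(t, 2))
    ]
    return PlantedCavitySpec(
        shell=shell,
        n_nodes=6,
        target_birth_index=12,
        target_death_index=13,
        fill_edges=[(0, 5)],
    )


def _padding_edges(spec: PlantedCavitySpec, n_needed: int) -> list[tuple[int, int]]:
    """Deterministic filler edges that can never alter the planted homology.

    Candidates are accepted only if they close no cycle once all shell
    nodes are identified to one supernode (union-find with the shell
    pre-merged), which guarantees padding adds neither independent cycles
    nor triangles at any filtration stage.
    """
    if n_needed == 0:
        return []
    parent = list(range(spec.n_nodes + 1))
    super_node = spec.n_nodes

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    shell_nodes = spec.shell_nodes()
    for v in shell_nodes:
        parent[find(v)] = find(super_node)
    taken = set(spec.shell_edges()) | {tuple(sorted(e)) for e in spec.fill_edges}
    pads: list[tuple[int, int]] = []
    for a, b in itertools.combinations(range(spec.n_nodes), 2):
        if (a, b) in taken:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        pads.append((a, b))
        if len(pads) == n_needed:
            return pads
    raise PlantedSpecError(
        f"cannot place {n_needed} inert padding edges on {spec.n_nodes} nodes; "
        "add auxiliary nodes or move the target indices"
    )


@dataclasses.dataclass
class PlantedGroundTruth:
    dimension: int
    birth_index: int
    death_index: int
    rho_birth: float
    rho_death: float
    shell_nodes: frozenset[int]
    birth_edge: tuple[int, int]


def planted_cavity_network(
    spec: PlantedCavitySpec,
) -> tuple[WeightedNetwork, PlantedGroundTruth]:
    """Realise a planted cavity with exact birth/death edge indices.

    Shell edges occupy the top weight ranks with the designated last shell
    edge exactly at ``target_birth_index``; inert padding edges (tree-like
    relative to the shell) fill any gaps; fill edges start at
    ``target_death_index``.  Weights are descending integers m..1 so the
    ordering, and hence the ground truth, is exact by construction.  The
    realised homology is verified with the boundary-rank oracle and a
    contradiction (e.g. a shell bounded before completion) is an error.
    """
    spec.validate()
    shell_edges = spec.shell_edges()
    birth_edge = shell_edges[-1]
    pre_birth = shell_edges[:-1]
    n_pad_before = spec.target_birth_index - len(shell_edges)
    n_pad_between = spec.target_death_index - spec.target_birth_index - 1
    pads = _padding_edges(spec, n_pad_before + n_pad_between)
    order: list[tuple[int, int]] = (
        pre_birth
        + pads[:n_pad_before]
        + [birth_edge]
        + pads[n_pad_before:]
        + [tuple(sorted(e)) for e in spec.fill_edges]
    )
    m = len(order)
    w = np.zeros((spec.n_nodes, spec.n_nodes))
    for rank, (a, b) in enumerate(order):
        w[a, b] = w[b, a] = float(m - rank)
    net = WeightedNetwork(w)

    filt = Filtration(spec.n_nodes, order, [float(m - r) for r in range(m)])
    k = spec.dimension
    b_before = betti_numbers_at(filt, spec.target_birth_index - 1, max_dim=k)[k]
    b_birth = betti_numbers_at(filt, spec.target_birth_index, max_dim=k)[k]
    b_death = betti_numbers_at(filt, spec.target_death_index, max_dim=k)[k]
    if not (b_before == 0 and b_birth == 1):
        raise PlantedSpecError(
            "shell bounded before completion or not born at the target index "
            f"(beta_{k} = {b_before} -> {b_birth})"
        )
    if b_death != 0:
        raise PlantedSpecError(
            f"first fill edge does not kill the cavity (beta_{k} = {b_death})"
        )
    npairs = net.n_pairs
    gt = PlantedGroundTruth(
        dimension=k,
        birth_index=spec.target_birth_index,
        death_index=spec.target_death_index,
        rho_birth=spec.target_birth_index / npairs,
        rho_death=spec.target_death_index / npairs,
        shell_nodes=frozenset(spec.shell_nodes()),
        birth_edge=birth_edge,
    )
    return net, gt


# ---------------------------------------------------------------------------
# perturbed scan ensembles


def perturb_scans(
    template: WeightedNetwork,
    n_scans: int,
    weight_jitter: float = 0.05,
    edge_flip_rate: float = 0.0,
    seed: int | None = None,
) -> list[WeightedNetwork]:
    """Noisy re-"scans" of a template network.

    Each scan multiplies every present weight by an independent log-normal
    factor exp(jitter * Z), deletes each present edge with probability
    ``edge_flip_rate``, and inserts each absent pair with the same
    probability at a weight drawn uniformly between the template's
    smallest and median positive weight.  With jitter only, the edge set
    is exactly the template's.
    """
    if not 0 <= weight_jitter:
        raise ValueError("weight_jitter must be non-negative")
    if not 0 <= edge_flip_rate < 1:
        raise ValueError("edge_flip_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = template.n_nodes
    iu = np.triu_indices(n, k=1)
    base = template.weights[iu]
    present = base > 0
    pos = base[present]
    lo, med = (float(pos.min()), float(np.median(pos))) if pos.size else (1.0, 1.0)
    scans = []
    for _ in range(n_scans):
        upper = base.copy()
        if weight_jitter > 0:
            factors = np.exp(weight_jitter * rng.standard_normal(base.shape))
            upper[present] = upper[present] * factors[present]
        if edge_flip_rate > 0:
            flips = rng.random(base.shape) < edge_flip_rate
            # delete flipped present edges, insert flipped absent pairs
            upper[present & flips] = 0.0
            ins = (~present) & flips
            upper[ins] = rng.uniform(lo, med, size=int(ins.sum()))
        w = np.zeros((n, n))
        w[iu] = upper
        w.T[iu] = upper
        scans.append(WeightedNetwork(w, list(template.node_ids), template.metadata))
    return scans
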