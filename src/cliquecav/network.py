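"""Weighted-network container, file IO, thresholding and group averaging.

Networks are undirected, weighted graphs stored as symmetric non-negative
matrices with zero diagonal; an edge is present iff its weight is positive.
Node metadata (anatomical name, 3D coordinate, cognitive-system label) rides
along as a pandas table keyed by node id.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-9

METADATA_COLUMNS = ["id", "name", "x", "y", "z", "system"]


class NetworkError(ValueError):
    """Invalid network input (asymmetry, negative weights, shape...)."""


@dataclasses.dataclass
class WeightedNetwork:
    """Symmetric, non-negative weighted graph with optional node metadata.

    Parameters
    ----------
    weights : (n, n) array
        Symmetric non-negative matrix with zero diagonal; entry (i, j) is
        the weight of edge i-j (e.g. streamline density between regions).
    node_ids : sequence of str, optional
        Ordered unique node labels; defaults to "n0".."n{n-1}".
    metadata : DataFrame, optional
        One row per node, aligned with ``node_ids``; recognised columns
        are name, x, y, z, system.
    """

    weights: np.ndarray
    node_ids: list[str] = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkError(f"adjacency matrix must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=SYMMETRY_TOL, rtol=0.0):
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise NetworkError(
                f"asymmetric input: entries ({i},{j})={w[i, j]} and ({j},{i})={w[j, i]}"
            )
        w = (w + w.T) / 2.0  # remove sub-tolerance asymmetry only
        if np.any(np.diag(w) != 0):
            raise NetworkError("nonzero diagonal: self-loops are not allowed")
        if np.any(w < 0):
            raise NetworkError("negative weights are not allowed")
        self.weights = w
        if self.node_ids is None:
            self.node_ids = [f"n{i}" for i in range(w.shape[0])]
        else:
            self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != w.shape[0]:
            raise NetworkError("node_ids length does not match matrix size")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise NetworkError("node_ids must be unique")
        if self.metadata is not None and len(self.metadata) != w.shape[0]:
            raise NetworkError(
                f"metadata rows ({len(self.metadata)}) do not match node count ({w.shape[0]})"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of possible edges n(n-1)/2 (the density denominator)."""
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths s_i = sum_j w_ij."""
        return self.weights.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def density(self) -> float:
        return self.n_edges / self.n_pairs

    def edges(self) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, w) for every present edge with i < j."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            yield i, j, float(self.weights[i, j])

    def to_graph(self, weighted: bool = True) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j, w in self.edges():
            if weighted:
                g.add_edge(i, j, weight=w)
            else:
                g.add_edge(i, j)
        return g

    def systems(self) -> dict[int, str] | None:
        """Node index -> cognitive-system label, if metadata carries one."""
        if self.metadata is None or "system" not in self.metadata.columns:
            return None
        return dict(enumerate(self.metadata["system"].astype(str)))

    def coordinates(self) -> np.ndarray | None:
        if self.metadata is None:
            return None
        if not {"x", "y", "z"}.issubset(self.metadata.columns):
            return None
        return self.metadata[["x", "y", "z"]].to_numpy(dtype=float)


@dataclasses.dataclass
class DensityThresholdedNetwork:
    """Binary network keeping the top-weight edges at edge density rho.

    ``retained_edges`` are the floor(rho * n(n-1)/2) highest-weight edges
    (capped at the number of present edges); every retained weight is >=
    every discarded weight.
    """

    parent: WeightedNetwork
    rho: float
    retained_edges: list[tuple[int, int]]

    @property
    def n_nodes(self) -> int:
        return self.parent.n_nodes

    @property
    def node_ids(self) -> list[str]:
        return self.parent.node_ids

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.retained_edges)
        return g

    def to_network(self) -> WeightedNetwork:
        """Weighted network restricted to the retained edge set."""
        w = np.zeros_like(self.parent.weights)
        for i, j in self.retained_edges:
            w[i, j] = w[j, i] = self.parent.weights[i, j]
        return WeightedNetwork(w, list(self.parent.node_ids), self.parent.metadata)


def _ranked_edges(net: WeightedNetwork) -> list[tuple[int, int]]:
    """Present edges sorted by decreasing weight, ties by node-pair order."""
    return sorted(
        ((i, j) for i, j, _ in net.edges()),
        key=lambda e: (-net.weights[e[0], e[1]], e[0], e[1]),
    )


def threshold_by_density(
    net: WeightedNetwork, rho: float, tiebreak: str = "lex"
) -> DensityThresholdedNetwork:
    """Keep the floor(rho * n(n-1)/2) highest-weight edges.

    The density denominator counts all unordered node pairs, including
    absent ones; when the requested count exceeds the number of present
    edges all present edges are retained.  With ``tiebreak='strict'`` a
    weight tie exactly at the cut boundary is an error instead of being
    broken by node-pair order.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    n_keep = min(int(np.floor(rho * net.n_pairs)), net.n_edges)
    ranked = _ranked_edges(net)
    if tiebreak == "strict" and 0 < n_keep < len(ranked):
        w_in = net.weights[ranked[n_keep - 1]]
        w_out = net.weights[ranked[n_keep]]
        if w_in == w_out:
            raise ValueError(
                f"weight tie ({w_in}) at the density cut; enable tie-breaking "
                "or perturb weights first"
            )
    return DensityThresholdedNetwork(net, rho, ranked[:n_keep])


def add_tiebreak_noise(
    net: WeightedNetwork, epsilon: float = 1e-4, seed: int | None = None
) -> WeightedNetwork:
    """Perturb each positive weight by an independent Uniform[0, epsilon] draw.

    Makes edge weights pairwise distinct with probability one so the
    weight-rank filtration is unambiguous; with a fixed seed the output is
    deterministic.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng(seed)
    w = net.weights.copy()
    iu = np.triu_indices(net.n_nodes, k=1)
    noise = rng.uniform(0.0, epsilon, size=len(iu[0]))
    mask = w[iu] > 0
    upper = w[iu]
    upper[mask] = upper[mask] + noise[mask]
    w[iu] = upper
    w.T[iu] = upper
    return WeightedNetwork(w, list(net.node_ids), net.metadata)


def group_average(nets: Sequence[WeightedNetwork]) -> WeightedNetwork:
    """Element-wise mean of weight matrices over a common node set.

    Zeros (absent edges) enter the mean, matching a group-averaged
    connectome where each edge is the mean streamline density over scans.
    """
    if len(nets) == 0:
        raise ValueError("need at least one network")
    ids = nets[0].node_ids
    for net in nets[1:]:
        if net.node_ids != ids:
            raise NetworkError("node sets differ between networks")
    w = np.mean([net.weights for net in nets], axis=0)
    meta = next((n.metadata for n in nets if n.metadata is not None), None)
    return WeightedNetwork(w, list(ids), meta)


# ---------------------------------------------------------------------------
# file IO: dense delimited matrices + metadata tables


def _sniff_delimiter(line: str) -> str | None:
    return "," if "," in line else None  # None -> any whitespace


def load_network(path: str | Path, metadata_path: str | Path | None = None) -> WeightedNetwork:
    """Read a dense square matrix (CSV or whitespace-delimited).

    An optional first header row carries node ids.  Metadata, if given, is
    a delimited table with columns id, name, x, y, z, system (any subset
    beyond id); rows are aligned to the matrix by the id column when node
    ids are present, else by order.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    tokens = first.strip().split(delim)
    try:
        [float(t) for t in tokens]
        header = False
    except ValueError:
        header = True
    if header:
        node_ids = [t.strip() for t in tokens]
        mat = np.loadtxt(path, delimiter=delim, skiprows=1)
    else:
        node_ids = None
        mat = np.loadtxt(path, delimiter=delim)
    mat = np.atleast_2d(mat)
    metadata = None
    if metadata_path is not None:
        metadata = load_metadata(metadata_path)
        if node_ids is not None:
            order = {str(v): k for k, v in enumerate(metadata["id"].astype(str))}
            missing = [nid for nid in node_ids if nid not in order]
            if missing:
                raise NetworkError(f"metadata is missing node ids: {missing[:5]}")
            metadata = metadata.iloc[[order[nid] for nid in node_ids]].reset_index(drop=True)
        elif len(metadata) == mat.shape[0]:
            node_ids = metadata["id"].astype(str).tolist()
    return WeightedNetwork(mat, node_ids, metadata)


def load_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=delim, engine="python")
    if "id" not in df.columns:
        raise NetworkError("metadata table must have an 'id' column")
    return df


def save_network(net: WeightedNetwork, path: str | Path, header: bool = True) -> None:
    """Write the dense weight matrix as CSV (full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(net.node_ids) + "\n")
        for row in net.weights:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def save_thresholded(tnet: DensityThresholdedNetwork, path: str | Path) -> None:
    """Save a thresholded network plus a sidecar recording rho and edge count."""
    path = Path(path)
    save_network(tnet.to_network(), path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    with open(sidecar, "w") as fh:
        fh.write(f"rho = {tnet.rho}\n")
        fh.write(f"retained_edges = {len(tnet.retained_edges)}\n")
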