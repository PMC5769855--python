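"""Maximal clique enumeration and node participation statistics.

A k-clique is a set of k all-to-all connected nodes; any subset is a face,
and a clique that is no other clique's face is maximal.  Node participation
P_k(v) counts the maximal k-cliques containing node v; P(v) sums over k.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import DensityThresholdedNetwork, WeightedNetwork

__all__ = [
    "maximal_cliques",
    "node_participation",
    "participation_by_group",
    "participation_difference",
]


def _binary_graph(net) -> nx.Graph:
    if isinstance(net, DensityThresholdedNetwork):
        return net.to_graph()
    if isinstance(net, WeightedNetwork):
        return net.to_graph(weighted=False)
    if isinstance(net, nx.Graph):
        return net
    raise TypeError(f"cannot interpret {type(net)!r} as a binary network")


def maximal_cliques(net) -> list[frozenset[int]]:
    """All maximal cliques of a binary network, isolated nodes included.

    Uses Bron-Kerbosch with pivoting; the output is duplicate-free and
    deterministically ordered (by size, then sorted node tuple).  Isolated
    nodes appear as maximal 1-cliques.
    """
    g = _binary_graph(net)
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    return sorted(cliques, key=lambda c: (len(c), tuple(sorted(c))))


def node_participation(
    cliques: list[frozenset[int]], n_nodes: int
) -> pd.DataFrame:
    """Participation table P_k(v): rows nodes, columns clique degree k.

    A trailing column ``P`` holds the row sum P(v).  Raises if a clique
    mentions a node outside 0..n_nodes-1.
    """
    if cliques:
        ks = sorted({len(c) for c in cliques})
    else:
        ks = []
    table = np.zeros((n_nodes, len(ks)), dtype=int)
    kindex = {k: a for a, k in enumerate(ks)}
    for c in cliques:
        for v in c:
            if not 0 <= v < n_nodes:
                raise ValueError(f"clique contains unknown node {v}")
            table[v, kindex[len(c)]] += 1
    df = pd.DataFrame(table, columns=[f"P{k}" for k in ks])
    df["P"] = table.sum(axis=1)
    return df


def participation_by_group(
    table: pd.DataFrame, labels: dict[int, str]
) -> pd.DataFrame:
    """Aggregate P_k(v) by cognitive-system label (sum within system)."""
    missing = [v for v in range(len(table)) if v not in labels]
    if missing:
        raise ValueError(f"unlabeled nodes: {missing[:5]}")
    df = table.copy()
    df["system"] = [labels[v] for v in range(len(table))]
    return df.groupby("system").sum().sort_index()


def participation_difference(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-node difference P_k^A(v) - P_k^B(v) (e.g. empirical minus null).

    Columns are the union of both tables' degrees; absent degrees count
    as zero.
    """
    cols = sorted(
        set(table_a.columns) | set(table_b.columns),
        key=lambda c: (len(c), c),
    )
    a = table_a.reindex(columns=cols, fill_value=0)
    b = table_b.reindex(columns=cols, fill_value=0)
    return a - b
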