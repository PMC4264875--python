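"""Local and global graph measures for binary and weighted networks.

Conventions follow the Brain Connectivity Toolbox family of definitions:

* binary — degree; average path length over reachable nodes (BFS distances);
  clustering C_i = 2 t_i / (k_i (k_i - 1)); local efficiency = global
  efficiency of the neighbour subgraph; nodal efficiency E_i = mean of 1/d_ij
  (unreachable pairs contribute 0); betweenness (Brandes), normalized by
  (n-1)(n-2)/2 so BC in [0, 1].
* weighted — strength s_i = sum_j w_ij; shortest paths on edge lengths 1/w;
  Onnela cube-root clustering on raw weights (weights are already in [0, 1]);
  cube-root weighted local efficiency with neighbour-subgraph distances;
  betweenness on 1/w lengths with the same normalization.

Isolated nodes (degree 0) are excluded: they carry ``included=False``, no
finite measure values, and do not enter any normalization or global mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryNetwork, WeightedNetwork

__all__ = [
    "NodeMeasures",
    "GlobalMeasures",
    "GLOBAL_MEASURE_NAMES",
    "node_measures",
    "global_measures",
    "global_from_network",
    "write_measures_tsv",
]

GLOBAL_MEASURE_NAMES = (
    "path_length",
    "clustering",
    "local_efficiency",
    "global_efficiency",
    "betweenness",
)

_LOCAL_COLUMNS = (
    "degree",
    "path_length",
    "clustering",
    "local_efficiency",
    "nodal_efficiency",
    "betweenness",
)


@dataclass(frozen=True)
class NodeMeasures:
    """Per-node measures; rows for isolated nodes are NaN with included=False."""

    table: pd.DataFrame
    kind: str  # "binary" | "weighted"

    @property
    def n_included(self) -> int:
        return int(self.table["included"].sum())


@dataclass(frozen=True)
class GlobalMeasures:
    path_length: float
    clustering: float
    local_efficiency: float
    global_efficiency: float
    betweenness: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLOBAL_MEASURE_NAMES}


def _efficiency_from_distances(dist: np.ndarray) -> np.ndarray:
    """Per-node mean of 1/d over other nodes; unreachable pairs contribute 0."""
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    m = dist.shape[0]
    return inv.sum(axis=1) / (m - 1) if m > 1 else np.zeros(m)


def _path_length_over_reachable(dist: np.ndarray) -> np.ndarray:
    m = dist.shape[0]
    out = np.zeros(m)
    for i in range(m):
        finite = np.isfinite(dist[i])
        finite[i] = False
        out[i] = dist[i, finite].mean() if finite.any() else np.nan
    return out


def _betweenness(lengths: np.ndarray | None, adjacency: np.ndarray) -> np.ndarray:
    """Brandes betweenness normalized by (n-1)(n-2)/2; ``lengths`` is an
    edge-length matrix (weighted case) or None (binary case)."""
    m = adjacency.shape[0]
    ii, jj = np.nonzero(np.triu(adjacency, 1))
    graph = ig.Graph(m, list(zip(ii.tolist(), jj.tolist())))
    weights = [float(lengths[i, j]) for i, j in zip(ii, jj)] if lengths is not None else None
    bc = np.asarray(graph.betweenness(weights=weights), dtype=float)
    if m > 2:
        bc /= (m - 1) * (m - 2) / 2
    return bc


def _binary_measures(adj: np.ndarray) -> pd.DataFrame:
    n = adj.shape[0]
    degree = adj.sum(axis=1)
    included = degree > 0
    table = pd.DataFrame(np.nan, index=range(n), columns=list(_LOCAL_COLUMNS))
    table["included"] = included
    idx = np.where(included)[0]
    m = len(idx)
    if m == 0:
        return table
    sub = adj[np.ix_(idx, idx)]
    k = sub.sum(axis=1)

    dist = shortest_path(csr_matrix(sub), method="D", unweighted=True, directed=False)
    path_len = _path_length_over_reachable(dist)
    eff = _efficiency_from_distances(dist)

    triangles = np.diag(sub @ sub @ sub) / 2.0
    clustering = np.zeros(m)
    mask = k >= 2
    clustering[mask] = 2.0 * triangles[mask] / (k[mask] * (k[mask] - 1.0))

    local_eff = np.zeros(m)
    for a in range(m):
        if k[a] < 2:
            continue
        nbrs = np.nonzero(sub[a])[0]
        block = sub[np.ix_(nbrs, nbrs)]
        d_sub = shortest_path(csr_matrix(block), method="D", unweighted=True, directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d_sub
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        local_eff[a] = inv.sum() / (len(nbrs) * (len(nbrs) - 1))

    bc = _betweenness(None, sub)

    table.loc[idx, "degree"] = k
    table.loc[idx, "path_length"] = path_len
    table.loc[idx, "clustering"] = clustering
    table.loc[idx, "local_efficiency"] = local_eff
    table.loc[idx, "nodal_efficiency"] = eff
    table.loc[idx, "betweenness"] = bc
    return table


def _weighted_measures(weights: np.ndarray) -> pd.DataFrame:
    n = weights.shape[0]
    support = (weights > 0).astype(float)
    degree = support.sum(axis=1)
    included = degree > 0
    table = pd.DataFrame(np.nan, index=range(n), columns=list(_LOCAL_COLUMNS))
    table["included"] = included
    idx = np.where(included)[0]
    m = len(idx)
    if m == 0:
        return table
    w = weights[np.ix_(idx, idx)]
    a = support[np.ix_(idx, idx)]
    k = a.sum(axis=1)
    strength = w.sum(axis=1)

    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    path_len = _path_length_over_reachable(dist)
    eff = _efficiency_from_distances(dist)

    w13 = np.cbrt(w)
    cyc = np.diag(w13 @ w13 @ w13)
    clustering = np.zeros(m)
    mask = k >= 2
    clustering[mask] = cyc[mask] / (k[mask] * (k[mask] - 1.0))

    local_eff = np.zeros(m)
    for u in range(m):
        if k[u] < 2:
            continue
        nbrs = np.nonzero(a[u])[0]
        block = lengths[np.ix_(nbrs, nbrs)]
        d_sub = shortest_path(csr_matrix(block), method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d_sub
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        cw = np.cbrt(w[u, nbrs])
        local_eff[u] = cw @ np.cbrt(inv) @ cw / (k[u] * (k[u] - 1.0))

    bc = _betweenness(lengths, a)

    table.loc[idx, "degree"] = strength
    table.loc[idx, "path_length"] = path_len
    table.loc[idx, "clustering"] = clustering
    table.loc[idx, "local_efficiency"] = local_eff
    table.loc[idx, "nodal_efficiency"] = eff
    table.loc[idx, "betweenness"] = bc
    return table


def node_measures(net: BinaryNetwork | WeightedNetwork) -> NodeMeasures:
    """All local measures of a binary or weighted network (isolated nodes excluded)."""
    if isinstance(net, BinaryNetwork):
        if net.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        return NodeMeasures(table=_binary_measures(net.adjacency), kind="binary")
    if isinstance(net, WeightedNetwork):
        if net.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if (net.weights < 0).any():
            raise ValueError("negative weights are not allowed")
        return NodeMeasures(table=_weighted_measures(net.weights), kind="weighted")
    raise TypeError(f"unsupported network type: {type(net).__name__}")


def global_measures(nm: NodeMeasures) -> GlobalMeasures:
    """Means of local measures over included (non-isolated) nodes."""
    rows = nm.table[nm.table["included"]]
    if len(rows) < 2:
        raise ValueError("fewer than 2 included (non-isolated) nodes")
    return GlobalMeasures(
        path_length=float(rows["path_length"].mean()),
        clustering=float(rows["clustering"].mean()),
        local_efficiency=float(rows["local_efficiency"].mean()),
        global_efficiency=float(rows["nodal_efficiency"].mean()),
        betweenness=float(rows["betweenness"].mean()),
    )


def global_from_network(net: BinaryNetwork | WeightedNetwork) -> GlobalMeasures:
    return global_measures(node_measures(net))


def write_measures_tsv(
    results: dict[str, tuple[NodeMeasures, GlobalMeasures]], path: str | Path
) -> None:
    """Tidy TSV: one row per (network id, node, measure) and (network id, global measure)."""
    rows = []
    for net_id, (nm, gm) in results.items():
        for node, record in nm.table.iterrows():
            for measure in _LOCAL_COLUMNS:
                rows.append((net_id, node, measure, record[measure]))
        for measure, value in gm.as_dict().items():
            rows.append((net_id, "global", measure, value))
    pd.DataFrame(rows, columns=["network", "node", "measure", "value"]).to_csv(
        path, sep="\t", index=False
    )
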