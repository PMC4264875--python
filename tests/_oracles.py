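"""Independent brute-force oracles for graph measures.

Everything here is written from first principles — Floyd–Warshall distances,
exhaustive triangle counting, explicit shortest-path enumeration for
betweenness — deliberately sharing no code path with the package, so tests
can compare the two implementations.
"""

from __future__ import annotations

import math

import numpy as np

INF = math.inf


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths; ``lengths[i][j]`` is the edge length (0 = no edge)."""
    n = lengths.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_shortest_paths(s: int, t: int, lengths: np.ndarray, dist: np.ndarray,
                             tol: float = 1e-9) -> list[list[int]]:
    """Every shortest path from s to t, found by recursive expansion."""
    if not math.isfinite(dist[s, t]):
        return []
    if s == t:
        return [[s]]
    paths = []
    n = lengths.shape[0]
    for v in range(n):
        if v != s and lengths[s, v] > 0:
            if abs(lengths[s, v] + dist[v, t] - dist[s, t]) <= tol:
                for tail in enumerate_shortest_paths(v, t, lengths, dist, tol):
                    paths.append([s] + tail)
    return paths


def betweenness_by_enumeration(lengths: np.ndarray) -> np.ndarray:
    """Normalized betweenness: fraction of shortest paths through each node,
    summed over unordered pairs and divided by (n-1)(n-2)/2."""
    n = lengths.shape[0]
    dist = floyd_warshall(lengths)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(s, t, lengths, dist)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                bc[v] += through / len(paths)
    if n > 2:
        bc /= (n - 1) * (n - 2) / 2
    return bc


def _mean_inverse_distance(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and math.isfinite(dist[i, j]) and dist[i, j] > 0:
                acc += 1.0 / dist[i, j]
        out[i] = acc / (n - 1) if n > 1 else 0.0
    return out


def _mean_reachable_distance(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        finite = [dist[i, j] for j in range(n) if j != i and math.isfinite(dist[i, j])]
        if finite:
            out[i] = sum(finite) / len(finite)
    return out


def binary_measures_oracle(adj: np.ndarray) -> dict[str, np.ndarray]:
    """All binary node measures on the included (degree > 0) subgraph.

    Returns full-length arrays with NaN at isolated nodes, mirroring the
    convention under test but computed independently.
    """
    n = adj.shape[0]
    degree_full = adj.sum(axis=1)
    included = degree_full > 0
    idx = [i for i in range(n) if included[i]]
    m = len(idx)
    out = {key: np.full(n, np.nan) for key in
           ("degree", "path_length", "clustering", "local_efficiency",
            "nodal_efficiency", "betweenness")}
    out["included"] = included
    if m == 0:
        return out
    sub = adj[np.ix_(idx, idx)]
    dist = floyd_warshall(sub)
    path_len = _mean_reachable_distance(dist)
    eff = _mean_inverse_distance(dist)
    bc = betweenness_by_enumeration(sub)

    k = sub.sum(axis=1)
    clustering = np.zeros(m)
    local_eff = np.zeros(m)
    for a in range(m):
        nbrs = [b for b in range(m) if sub[a, b] > 0]
        if len(nbrs) < 2:
            continue
        triangles = 0
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                if sub[nbrs[x], nbrs[y]] > 0:
                    triangles += 1
        clustering[a] = 2.0 * triangles / (k[a] * (k[a] - 1))
        block = sub[np.ix_(nbrs, nbrs)]
        d_sub = floyd_warshall(block)
        acc = 0.0
        for x in range(len(nbrs)):
            for y in range(len(nbrs)):
                if x != y and math.isfinite(d_sub[x, y]) and d_sub[x, y] > 0:
                    acc += 1.0 / d_sub[x, y]
        local_eff[a] = acc / (len(nbrs) * (len(nbrs) - 1))

    for pos, node in enumerate(idx):
        out["degree"][node] = k[pos]
        out["path_length"][node] = path_len[pos]
        out["clustering"][node] = clustering[pos]
        out["local_efficiency"][node] = local_eff[pos]
        out["nodal_efficiency"][node] = eff[pos]
        out["betweenness"][node] = bc[pos]
    return out


def weighted_measures_oracle(weights: np.ndarray) -> dict[str, np.ndarray]:
    """Weighted node measures: 1/w path lengths, Onnela cube-root clustering,
    cube-root local efficiency with neighbour-subgraph distances."""
    n = weights.shape[0]
    support = weights > 0
    degree_full = support.sum(axis=1)
    included = degree_full > 0
    idx = [i for i in range(n) if included[i]]
    m = len(idx)
    out = {key: np.full(n, np.nan) for key in
           ("degree", "path_length", "clustering", "local_efficiency",
            "nodal_efficiency", "betweenness")}
    out["included"] = included
    if m == 0:
        return out
    w = weights[np.ix_(idx, idx)]
    lengths = np.where(w > 0, np.divide(1.0, w, out=np.zeros_like(w), where=w > 0), 0.0)
    dist = floyd_warshall(lengths)
    path_len = _mean_reachable_distance(dist)
    eff = _mean_inverse_distance(dist)
    bc = betweenness_by_enumeration(lengths)

    k = (w > 0).sum(axis=1)
    strength = w.sum(axis=1)
    clustering = np.zeros(m)
    local_eff = np.zeros(m)
    for a in range(m):
        nbrs = [b for b in range(m) if w[a, b] > 0]
        if len(nbrs) < 2:
            continue
        acc = 0.0
        for x in range(len(nbrs)):
            for y in range(len(nbrs)):
                if x != y:
                    acc += (w[a, nbrs[x]] * w[a, nbrs[y]] * w[nbrs[x], nbrs[y]]) ** (1 / 3)
        clustering[a] = acc / (k[a] * (k[a] - 1))
        block = lengths[np.ix_(nbrs, nbrs)]
        d_sub = floyd_warshall(block)
        acc = 0.0
        for x in range(len(nbrs)):
            for y in range(len(nbrs)):
                if x != y and math.isfinite(d_sub[x, y]) and d_sub[x, y] > 0:
                    acc += (w[a, nbrs[x]] * w[a, nbrs[y]] / d_sub[x, y]) ** (1 / 3)
        local_eff[a] = acc / (k[a] * (k[a] - 1))

    for pos, node in enumerate(idx):
        out["degree"][node] = strength[pos]
        out["path_length"][node] = path_len[pos]
        out["clustering"][node] = clustering[pos]
        out["local_efficiency"][node] = local_eff[pos]
        out["nodal_efficiency"][node] = eff[pos]
        out["betweenness"][node] = bc[pos]
    return out


def icc_oracle(values: np.ndarray) -> float:
    """Explicit sum-of-squares one-way ANOVA ICC, written out longhand."""
    values = np.asarray(values, dtype=float)
    k, s = values.shape
    grand = values.sum() / (k * s)
    ss_between = 0.0
    for j in range(s):
        mean_j = sum(values[i, j] for i in range(k)) / k
        ss_between += k * (mean_j - grand) ** 2
    ss_within = 0.0
    for j in range(s):
        mean_j = sum(values[i, j] for i in range(k)) / k
        for i in range(k):
            ss_within += (values[i, j] - mean_j) ** 2
    bms = ss_between / (s - 1)
    ems = ss_within / (s * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


def set_partitions(items: list[int]):
    """All set partitions of ``items`` (exhaustive, recursive)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def partition_to_labels(partition: list[list[int]], n: int) -> dict[int, int]:
    labels = {}
    for c, block in enumerate(partition):
        for node in block:
            labels[node] = c
    assert len(labels) == n
    return labels
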