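"""Hub scoring, hub co-occurrence, community co-assignment, scaled inclusivity
and degree/weight-preserving null networks.

Hubs are nodes scoring >= 2 on four criteria: membership in the top 20% by
(1) degree/strength and (2) betweenness centrality, and the bottom 20% by
(3) clustering (restricted to nodes of degree >= 2, where clustering is
defined) and (4) average path length.  The 20% cut uses ceil(0.2 * n_included)
with boundary ties all flagged, so the result is deterministic and
order-independent.

Community structure is summarized by a probabilistic co-assignment matrix:
modularity maximization (Louvain-style greedy agglomeration) is run repeatedly
from seeded random node orders, and each realization contributes a 0/1
same-community indicator matrix; averaging over realizations yields per-pair
co-assignment probabilities.

Consistency of communities between two networks is quantified per node by
scaled inclusivity, SI = |C_A ∩ C_B|^2 / (|C_A| |C_B|), and by its
probabilistic extension computed directly from two co-assignment matrices,

    pSI_i = (sum_j P^A_ij P^B_ij)^2 / ((sum_j P^A_ij)(sum_j P^B_ij)),

with sums including the diagonal; on binarized (hard-partition) matrices pSI
reduces exactly to SI.  Significance is assessed against rewired null
networks: Maslov–Sneppen double-edge swaps preserving the degree sequence
(binary) or rewiring the support and permuting the original weight multiset
(weighted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import BinaryNetwork, WeightedNetwork
from .measures import NodeMeasures

__all__ = [
    "HubResult",
    "CoAssignmentMatrix",
    "NullEnsemble",
    "hub_score",
    "hub_cooccurrence",
    "detect_communities",
    "scaled_inclusivity",
    "scaled_inclusivity_all",
    "probabilistic_si",
    "coassignment_from_partition",
    "consensus_coassignment",
    "null_ensemble",
    "null_pvalue",
]

_HUB_CRITERIA = ("high_degree", "high_betweenness", "low_clustering", "low_path_length")


@dataclass(frozen=True)
class HubResult:
    flags: pd.DataFrame  # one 0/1 column per criterion, plus hub_score
    hubs: frozenset[int]


@dataclass(frozen=True)
class CoAssignmentMatrix:
    prob: np.ndarray
    n_realizations: int

    def __post_init__(self) -> None:
        p = self.prob
        if not np.allclose(p, p.T):
            raise ValueError("co-assignment matrix must be symmetric")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("co-assignment entries must lie in [0, 1]")
        if not np.allclose(np.diag(p), 1.0):
            raise ValueError("co-assignment diagonal must be 1")

    @property
    def n_nodes(self) -> int:
        return self.prob.shape[0]


@dataclass(frozen=True)
class NullEnsemble:
    networks: list
    mode: str  # "degree" | "weight"


def _top_flags(values: np.ndarray, eligible: np.ndarray, n_flag: int, largest: bool) -> np.ndarray:
    """Flag the n_flag best eligible nodes; boundary ties are all flagged."""
    flags = np.zeros(len(values), dtype=bool)
    pool = np.where(eligible)[0]
    if len(pool) == 0:
        return flags
    vals = values[pool]
    order = np.argsort(-vals if largest else vals, kind="stable")
    cutoff_rank = min(n_flag, len(pool)) - 1
    cutoff = vals[order[cutoff_rank]]
    flags[pool] = vals >= cutoff if largest else vals <= cutoff
    return flags


def hub_score(nm: NodeMeasures) -> HubResult:
    """Four-criterion hub score on included nodes; hubs have score >= 2."""
    table = nm.table
    included = table["included"].to_numpy(dtype=bool)
    n_inc = int(included.sum())
    if n_inc < 5:
        raise ValueError(f"need at least 5 included nodes for a top-20% cut, got {n_inc}")
    n_flag = math.ceil(0.2 * n_inc)

    degree = np.nan_to_num(table["degree"].to_numpy(dtype=float))
    betweenness = np.nan_to_num(table["betweenness"].to_numpy(dtype=float))
    clustering = np.nan_to_num(table["clustering"].to_numpy(dtype=float))
    path_length = np.nan_to_num(table["path_length"].to_numpy(dtype=float), nan=np.inf)
    # clustering criterion only makes sense where clustering is defined
    binary_degree = np.zeros(len(table))
    binary_degree[included] = np.maximum(degree[included], 0)
    deg_ok = included & (binary_degree >= 2) if nm.kind == "binary" else included

    flags = pd.DataFrame(
        {
            "high_degree": _top_flags(degree, included, n_flag, largest=True),
            "high_betweenness": _top_flags(betweenness, included, n_flag, largest=True),
            "low_clustering": _top_flags(clustering, deg_ok, n_flag, largest=False),
            "low_path_length": _top_flags(path_length, included, n_flag, largest=False),
        }
    ).astype(int)
    flags["hub_score"] = flags[list(_HUB_CRITERIA)].sum(axis=1)
    hubs = frozenset(int(i) for i in np.where(flags["hub_score"] >= 2)[0])
    return HubResult(flags=flags, hubs=hubs)


def hub_cooccurrence(hubs_a: set[int], hubs_b: set[int], method: str = "dice") -> float:
    """Hub-set agreement: Dice 2|A∩B|/(|A|+|B|) by default, or Jaccard.

    1 for identical non-empty sets, 0 for disjoint non-empty sets; defined as
    1 when both sets are empty.
    """
    a, b = set(hubs_a), set(hubs_b)
    if not a and not b:
        return 1.0
    if method == "dice":
        return 2.0 * len(a & b) / (len(a) + len(b))
    if method == "jaccard":
        return len(a & b) / len(a | b)
    raise ValueError(f"unknown method {method!r}")


def _as_graph(net: BinaryNetwork | WeightedNetwork) -> tuple[nx.Graph, str | None]:
    graph = nx.Graph()
    if isinstance(net, BinaryNetwork):
        mat, weight = net.adjacency, None
    elif isinstance(net, WeightedNetwork):
        mat, weight = net.weights, "weight"
    else:
        raise TypeError(f"unsupported network type: {type(net).__name__}")
    graph.add_nodes_from(range(mat.shape[0]))
    ii, jj = np.nonzero(np.triu(mat, 1))
    for i, j in zip(ii, jj):
        graph.add_edge(int(i), int(j), weight=float(mat[i, j]))
    return graph, weight


def coassignment_from_partition(partition: dict[int, int] | np.ndarray) -> np.ndarray:
    """0/1 same-community indicator matrix of a hard partition."""
    if isinstance(partition, dict):
        labels = np.array([partition[i] for i in sorted(partition)])
    else:
        labels = np.asarray(partition)
    return (labels[:, None] == labels[None, :]).astype(float)


def detect_communities(
    net: BinaryNetwork | WeightedNetwork, n_realizations: int, seed: int
) -> CoAssignmentMatrix:
    """Probabilistic co-assignment matrix from repeated seeded modularity runs.

    Each realization permutes the node order with the seeded RNG, runs Louvain
    modularity maximization, and records the 0/1 co-assignment matrix; the
    average over realizations gives per-pair co-assignment probabilities.
    """
    graph, weight = _as_graph(net)
    n = graph.number_of_nodes()
    if graph.number_of_edges() == 0:
        raise ValueError("cannot detect communities in an empty graph")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    total = np.zeros((n, n))
    for _ in range(n_realizations):
        perm = rng.permutation(n)
        relabel = {int(old): int(new) for old, new in zip(range(n), perm)}
        shuffled = nx.relabel_nodes(graph, relabel, copy=True)
        comms = nx.community.louvain_communities(
            shuffled, weight=weight, seed=int(rng.integers(2**31 - 1))
        )
        labels = np.empty(n, dtype=int)
        inverse = np.argsort(perm)
        for c, members in enumerate(comms):
            for node in members:
                labels[inverse[node]] = c
        total += coassignment_from_partition(labels)
    prob = total / n_realizations
    np.fill_diagonal(prob, 1.0)
    return CoAssignmentMatrix(prob=prob, n_realizations=n_realizations)


def scaled_inclusivity(
    part_a: dict[int, int], part_b: dict[int, int], node: int
) -> float:
    """SI of one node between two hard partitions: |C_A ∩ C_B|^2 / (|C_A| |C_B|)."""
    if node not in part_a or node not in part_b:
        raise KeyError(f"node {node} missing from a partition")
    mod_a = {k for k, v in part_a.items() if v == part_a[node]}
    mod_b = {k for k, v in part_b.items() if v == part_b[node]}
    return len(mod_a & mod_b) ** 2 / (len(mod_a) * len(mod_b))


def scaled_inclusivity_all(part_a: dict[int, int], part_b: dict[int, int]) -> np.ndarray:
    nodes = sorted(part_a)
    if sorted(part_b) != nodes:
        raise ValueError("partitions must cover the same node set")
    return np.array([scaled_inclusivity(part_a, part_b, v) for v in nodes])


def probabilistic_si(
    coassign_a: CoAssignmentMatrix, coassign_b: CoAssignmentMatrix
) -> tuple[np.ndarray, float]:
    """Per-node pSI and its mean from two probabilistic co-assignment matrices."""
    if coassign_a.n_nodes != coassign_b.n_nodes:
        raise ValueError("co-assignment matrices must share the node set")
    pa, pb = coassign_a.prob, coassign_b.prob
    overlap = (pa * pb).sum(axis=1)
    psi = overlap**2 / (pa.sum(axis=1) * pb.sum(axis=1))
    return psi, float(psi.mean())


def consensus_coassignment(
    coassigns: list[CoAssignmentMatrix], stable_threshold: float = 0.95
) -> tuple[CoAssignmentMatrix, list[frozenset[int]]]:
    """Entrywise-mean consensus matrix plus stable groups.

    Stable groups are the connected components (of size >= 2) of the graph of
    node pairs whose consensus co-assignment probability is >= the threshold.
    """
    if len(coassigns) < 2:
        raise ValueError("need at least two co-assignment matrices")
    n = coassigns[0].n_nodes
    for c in coassigns[1:]:
        if c.n_nodes != n:
            raise ValueError("mismatched node sets")
    mean = np.mean([c.prob for c in coassigns], axis=0)
    np.fill_diagonal(mean, 1.0)
    consensus = CoAssignmentMatrix(
        prob=mean, n_realizations=sum(c.n_realizations for c in coassigns)
    )
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(mean >= stable_threshold, 1))
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
    groups = [
        frozenset(comp) for comp in nx.connected_components(graph) if len(comp) >= 2
    ]
    return consensus, sorted(groups, key=min)


# ---------------------------------------------------------------------------
# null networks


def _rewire_edges(
    edges: list[tuple[int, int]], rng: np.random.Generator, n_attempts: int
) -> list[tuple[int, int]]:
    """Maslov–Sneppen double-edge swaps on an undirected simple edge list."""
    edges = [tuple(sorted(e)) for e in edges]
    present = set(edges)
    n_edges = len(edges)
    pick = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b or a == c or b == d:
            continue
        new1, new2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if new1 in present or new2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(new1)
        present.add(new2)
        edges[e1], edges[e2] = new1, new2
    return edges


def null_ensemble(
    net: BinaryNetwork | WeightedNetwork,
    n_realizations: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Rewired null networks preserving degrees (binary) or weights (weighted).

    Binary nulls apply ``swaps_per_edge * E`` attempted double-edge swaps, so
    every node keeps its exact degree.  Weighted nulls rewire the binarized
    support the same way and then place a random permutation of the original
    weight multiset on the new edges, preserving the weight distribution
    exactly.
    """
    if isinstance(net, BinaryNetwork):
        mat, mode = net.adjacency, "degree"
    elif isinstance(net, WeightedNetwork):
        mat, mode = net.weights, "weight"
    else:
        raise TypeError(f"unsupported network type: {type(net).__name__}")
    n = mat.shape[0]
    ii, jj = np.nonzero(np.triu(mat, 1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    if mode == "degree" and len(edges) < 2:
        raise ValueError("need at least 2 edges for a degree-preserving swap")
    if mode == "weight" and len(edges) < 1:
        raise ValueError("need at least 1 edge to rewire a weighted network")
    weights = mat[ii, jj]
    n_attempts = swaps_per_edge * len(edges)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    nulls = []
    for _ in range(n_realizations):
        rewired = _rewire_edges(edges, rng, n_attempts)
        new = np.zeros((n, n))
        if mode == "degree":
            for a, b in rewired:
                new[a, b] = new[b, a] = 1.0
            nulls.append(
                BinaryNetwork(adjacency=new, density=net.density, node_labels=net.node_labels)
            )
        else:
            shuffled = weights[rng.permutation(len(weights))]
            for (a, b), w in zip(rewired, shuffled):
                new[a, b] = new[b, a] = w
            nulls.append(WeightedNetwork(weights=new, node_labels=net.node_labels))
    return NullEnsemble(networks=nulls, mode=mode)


def null_pvalue(observed: float, null_values) -> float:
    """Upper-tail empirical p-value with add-one correction: (1 + #{null >= obs}) / (1 + N)."""
    null_values = np.asarray(list(null_values), dtype=float)
    return float((1 + (null_values >= observed).sum()) / (1 + len(null_values)))
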