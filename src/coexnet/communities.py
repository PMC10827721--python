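"""Random-walk (walktrap) community detection.

Short random walks of length ``t`` tend to stay inside densely connected
subgraphs, so the rows of ``P^t`` (``P = D^-1 A``) act as node
signatures. Communities are merged agglomeratively, always joining the
adjacent pair whose merge least increases the within-community variance
of those signatures (Ward-style cost), and the reported partition is the
merge step with maximal modularity Q.

Nodes of degree zero have no defined walk distribution; they are kept as
singleton communities outside the merge process.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .diffexpr import GeneSet

__all__ = [
    "MergeTree",
    "CommunityPartition",
    "walktrap_dendrogram",
    "modularity",
    "best_partition",
    "large_communities",
]


@dataclass
class CommunityPartition:
    """node -> community label, with the partition's modularity Q."""

    labels: dict
    q: float
    sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            sizes: dict = {}
            for c in self.labels.values():
                sizes[c] = sizes.get(c, 0) + 1
            self.sizes = sizes

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    def members(self, community) -> list:
        return [v for v, c in self.labels.items() if c == community]


@dataclass
class MergeTree:
    """Agglomeration record: initial singleton communities and the merge
    sequence, with the merge cost (delta sigma) and modularity after
    each step.

    ``merges[k] = (left_id, right_id, new_id, dsigma, q_after)``;
    community ids 0..n-1 are the initial singletons (in ``nodes`` order)
    and new ids continue from n.
    """

    nodes: list
    merges: list
    q_profile: list  # q_profile[0] = singleton partition, then one per merge
    m_edges: int

    def partition_at(self, step: int) -> CommunityPartition:
        """Partition after the first ``step`` merges (0 = singletons)."""
        if not 0 <= step <= len(self.merges):
            raise ValueError("step out of range")
        n = len(self.nodes)
        parent = list(range(n + len(self.merges)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for left, right, new_id, _, _ in self.merges[:step]:
            parent[find(left)] = new_id
            parent[find(right)] = new_id
        roots = {}
        labels = {}
        for idx, v in enumerate(self.nodes):
            r = find(idx)
            labels[v] = roots.setdefault(r, len(roots))
        return CommunityPartition(labels, q=float(self.q_profile[step]))


def _walk_matrix(net: nx.Graph, nodes: list, t: int, weighted: bool) -> np.ndarray:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        w = float(abs(data.get("rho", 1.0))) if weighted else 1.0
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    deg = a.sum(axis=1)
    p = a / deg[:, None]
    return np.linalg.matrix_power(p, t), deg


def walktrap_dendrogram(net: nx.Graph, steps: int = 4, weighted: bool = False) -> MergeTree:
    """Build the walktrap merge dendrogram.

    At every step the two *adjacent* communities with the smallest merge
    cost ``dsigma = (1/n) * |C1||C2|/(|C1|+|C2|) * r2(C1, C2)`` are
    joined, where ``r2`` is the degree-weighted squared distance between
    the communities' t-step walk distributions; community distributions
    are size-weighted averages of their members'. Components never merge
    with each other, so a graph with c components ends with c
    communities (plus degree-zero singletons).
    """
    if steps < 1:
        raise ValueError("walk length must be >= 1")
    all_nodes = list(net.nodes)
    if not all_nodes:
        raise ValueError("empty graph")
    walk_nodes = [v for v in all_nodes if net.degree(v) > 0]
    m = net.number_of_edges()
    node_order = walk_nodes + [v for v in all_nodes if v not in set(walk_nodes)]
    n_all = len(node_order)
    if m == 0:
        return MergeTree(nodes=node_order, merges=[], q_profile=[0.0], m_edges=0)

    nw = len(walk_nodes)
    pt, deg = _walk_matrix(net, walk_nodes, steps, weighted)
    inv_deg = 1.0 / deg
    index = {v: i for i, v in enumerate(walk_nodes)}

    # community state; ids 0..n_all-1 are singletons in node_order
    rows: dict[int, np.ndarray] = {i: pt[i] for i in range(nw)}
    size = {i: 1 for i in range(n_all)}
    # modularity bookkeeping is always on edge counts (unweighted)
    degree_total = {
        i: (float(net.degree(node_order[i])) if i < nw else 0.0) for i in range(n_all)
    }
    internal = {i: 0.0 for i in range(n_all)}
    alive = set(range(n_all))
    neighbors: dict[int, dict[int, float]] = {i: {} for i in range(n_all)}
    for u, v in net.edges:
        i, j = index[u], index[v]
        if i == j:
            continue
        neighbors[i][j] = neighbors[i].get(j, 0.0) + 1.0
        neighbors[j][i] = neighbors[j].get(i, 0.0) + 1.0

    def dsigma(i: int, j: int) -> float:
        diff = rows[i] - rows[j]
        r2 = float(np.dot(diff * diff, inv_deg))
        si, sj = size[i], size[j]
        return (si * sj) / (si + sj) / nw * r2

    heap: list = []
    for i in range(nw):
        for j in neighbors[i]:
            if i < j:
                heapq.heappush(heap, (dsigma(i, j), i, j))

    two_m = 2.0 * m
    q = -sum((degree_total[i] / two_m) ** 2 for i in range(n_all))
    q_profile = [q]
    merges = []
    next_id = n_all

    while heap:
        cost, i, j = heapq.heappop(heap)
        if i not in alive or j not in alive or j not in neighbors[i]:
            continue
        new = next_id
        next_id += 1
        si, sj = size[i], size[j]
        rows[new] = (si * rows[i] + sj * rows[j]) / (si + sj)
        size[new] = si + sj
        between = neighbors[i][j]
        internal[new] = internal[i] + internal[j] + between
        degree_total[new] = degree_total[i] + degree_total[j]
        q += between / m - 2.0 * (degree_total[i] / two_m) * (degree_total[j] / two_m)

        merged_nbrs: dict[int, float] = {}
        for old in (i, j):
            for k, cnt in neighbors[old].items():
                if k in (i, j):
                    continue
                merged_nbrs[k] = merged_nbrs.get(k, 0.0) + cnt
        for old in (i, j):
            for k in neighbors[old]:
                if k not in (i, j):
                    neighbors[k].pop(old, None)
            del neighbors[old]
            alive.discard(old)
            rows.pop(old, None)
        neighbors[new] = merged_nbrs
        for k in merged_nbrs:
            neighbors[k][new] = merged_nbrs[k]
        alive.add(new)
        for k in merged_nbrs:
            a, b = (new, k) if new < k else (k, new)
            heapq.heappush(heap, (dsigma(a, b), a, b))

        merges.append((i, j, new, float(cost), float(q)))
        q_profile.append(float(q))

    return MergeTree(nodes=node_order, merges=merges, q_profile=q_profile, m_edges=m)


def modularity(net: nx.Graph, partition: CommunityPartition) -> float:
    """Newman modularity ``Q = sum_c (e_c/m - (d_c/2m)^2)``.

    ``e_c`` counts intra-community edges, ``d_c`` the total degree of
    community c. Requires at least one edge and a partition covering
    every node.
    """
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    missing = set(net.nodes) - set(partition.labels)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    intra: dict = {}
    degs: dict = {}
    for v in net.nodes:
        c = partition.labels[v]
        degs[c] = degs.get(c, 0) + net.degree(v)
    for u, v in net.edges:
        if partition.labels[u] == partition.labels[v]:
            c = partition.labels[u]
            intra[c] = intra.get(c, 0) + 1
    two_m = 2.0 * m
    return float(
        sum(intra.get(c, 0) / m - (degs[c] / two_m) ** 2 for c in degs)
    )


def best_partition(tree: MergeTree) -> CommunityPartition:
    """The merge step with maximal modularity; ties resolved toward
    fewer communities (the later step)."""
    best_step = 0
    best_q = tree.q_profile[0]
    for step, q in enumerate(tree.q_profile):
        if q >= best_q - 1e-12:
            if q > best_q + 1e-12 or step > best_step:
                best_step, best_q = step, q
    return tree.partition_at(best_step)


def large_communities(
    partition: CommunityPartition, min_size: int = 100, prefix: str = "C"
) -> list[GeneSet]:
    """Communities with >= min_size members, largest first, relabelled
    C1..Ck deterministically (size descending, then lexicographic
    smallest member)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    groups: dict = {}
    for v, c in partition.labels.items():
        groups.setdefault(c, []).append(v)
    big = [sorted(vs) for vs in groups.values() if len(vs) >= min_size]
    big.sort(key=lambda vs: (-len(vs), vs[0]))
    return [
        GeneSet(label=f"{prefix}{i}", genes=frozenset(vs), direction="any")
        for i, vs in enumerate(big, start=1)
    ]
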