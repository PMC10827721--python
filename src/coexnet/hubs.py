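"""Hub-gene scoring and network robustness.

A node's hub score is the product of three centralities — degree,
closeness, and HITS authority (eigenvector centrality on an undirected
graph) — so a hub must be locally connected, globally reachable, and
attached to other well-connected nodes at once. The top-k nodes per
community are candidate regulator genes; removing them and re-measuring
cohesion (components, diameter, mean geodesic distance) quantifies how
much the network depends on them, optionally against a random-removal
baseline of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .communities import CommunityPartition
from .diffexpr import GeneSet

__all__ = [
    "CohesionReport",
    "centralities",
    "hub_scores",
    "select_hubs",
    "cohesion_stats",
    "removal_report",
]


def _adjacency(net: nx.Graph):
    nodes = list(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for u, v in net.edges:
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return nodes, adj


def _power_iteration(adj: sp.csr_matrix, tol: float, max_iter: int) -> np.ndarray:
    n = adj.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        # 0.5 I shift breaks two-cycles on bipartite components without
        # changing eigenvectors
        y = adj @ x + 0.5 * x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(n)
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            return np.abs(y)
        x = y
    raise RuntimeError(
        f"authority power iteration did not converge in {max_iter} steps"
    )


def _authority(adj: sp.csr_matrix, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Eigenvector-centrality authority, computed per connected component.

    Each component's principal adjacency eigenvector (power iteration
    with a 0.5 I shift, L2-renormalized per step) is reported with
    max-norm 1 inside the component; isolated nodes get 0. Per-component
    computation keeps the score well-defined on the multi-component
    graphs that thresholded co-expression networks typically are, where
    a single global eigenvector would be degenerate across near-equal
    components.
    """
    from scipy.sparse.csgraph import connected_components

    n = adj.shape[0]
    out = np.zeros(n)
    if adj.nnz == 0:
        return out
    _, labels = connected_components(adj, directed=False)
    for comp in np.unique(labels):
        idx = np.where(labels == comp)[0]
        if idx.size == 1:
            continue
        sub = adj[np.ix_(idx, idx)]
        vec = _power_iteration(sub.tocsr(), tol, max_iter)
        peak = vec.max()
        if peak > 0:
            out[idx] = vec / peak
    return out


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, within-component closeness, and authority per node.

    closeness(v) = (|C_v| - 1) / sum of geodesics from v within its
    component (0 for isolated nodes); authority is the principal
    adjacency eigenvector of v's connected component, scaled to max 1
    per component (0 for isolated nodes).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes, adj = _adjacency(net)
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    finite = np.isfinite(dist)
    comp_size = finite.sum(axis=1)  # includes self
    dsum = np.where(finite, dist, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        closeness = np.where(comp_size > 1, (comp_size - 1) / dsum, 0.0)
    auth = _authority(adj)
    return pd.DataFrame(
        {
            "degree": [net.degree(v) for v in nodes],
            "closeness": closeness,
            "authority": auth,
        },
        index=pd.Index(nodes, name="gene_id"),
    )


def hub_scores(cent: pd.DataFrame) -> pd.DataFrame:
    """Composite score = degree * closeness * authority, with
    deterministic descending ranks (ties broken by gene id)."""
    out = cent.copy()
    out["score"] = out["degree"] * out["closeness"] * out["authority"]
    order = sorted(out.index, key=lambda g: (-out.at[g, "score"], str(g)))
    out = out.loc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_hubs(
    partition: CommunityPartition,
    scores: pd.DataFrame,
    k: int = 50,
    communities=None,
) -> pd.DataFrame:
    """Top-k nodes per community by hub rank.

    ``communities`` may be GeneSet objects (e.g. from
    ``large_communities``) or raw partition labels; default is every
    community in the partition. Communities smaller than k contribute
    all their members. Returns a DataFrame gene_id, community, score,
    rank ordered by (community, rank).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if communities is None:
        comm_members = {}
        for v, c in partition.labels.items():
            comm_members.setdefault(c, []).append(v)
        named = [(str(c), vs) for c, vs in sorted(comm_members.items(), key=lambda x: str(x[0]))]
    else:
        named = []
        labels = set(partition.labels.values())
        for c in communities:
            if isinstance(c, GeneSet):
                named.append((c.label, sorted(c.genes)))
            else:
                if c not in labels:
                    raise ValueError(f"unknown community label: {c!r}")
                named.append((str(c), partition.members(c)))
    rows = []
    for label, members in named:
        members = [g for g in members if g in scores.index]
        ranked = scores.loc[members].sort_values("rank").head(k)
        for g in ranked.index:
            rows.append(
                {
                    "gene_id": g,
                    "community": label,
                    "score": float(ranked.at[g, "score"]),
                    "rank": int(ranked.at[g, "rank"]),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "community", "score", "rank"])


def cohesion_stats(net: nx.Graph) -> dict:
    """Cohesion measures: size, density, components, diameter of the
    largest component, mean geodesic over reachable pairs, and the
    fraction of unreachable pairs (reported separately so the mean stays
    finite)."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    out = {
        "n_nodes": n,
        "n_edges": m,
        "density": (2.0 * m / (n * (n - 1)) if n > 1 else 0.0),
    }
    if n == 0:
        out.update(n_components=0, diameter=0, mean_geodesic=0.0, unreachable_fraction=0.0)
        return out
    _, adj = _adjacency(net)
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    reachable = int(finite.sum())  # ordered pairs
    total_pairs = n * (n - 1)
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(adj, directed=False)
    out["n_components"] = int(n_comp)
    out["diameter"] = int(dist[finite].max()) if reachable else 0
    out["mean_geodesic"] = float(dist[finite].mean()) if reachable else 0.0
    out["unreachable_fraction"] = (
        float((total_pairs - reachable) / total_pairs) if total_pairs else 0.0
    )
    return out


@dataclass
class CohesionReport:
    """Before/after cohesion of a network under node removal, with an
    optional size-matched random-removal baseline."""

    before: dict
    after: dict
    removed: list
    baseline: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def removal_report(
    net: nx.Graph,
    remove,
    baseline_repeats: int = 0,
    seed: int | None = None,
) -> CohesionReport:
    """Cohesion before and after deleting the given nodes.

    With ``baseline_repeats > 0``, the same number of nodes is drawn
    uniformly (without replacement) from the *non-removed* nodes per
    repeat, and the baseline distribution of diameter and mean geodesic
    is summarized as mean and sd — a paired yardstick for whether the
    targeted removal fragments the network more than chance.
    """
    remove_set = set(remove.genes if isinstance(remove, GeneSet) else remove)
    nodes = set(net.nodes)
    unknown = remove_set - nodes
    if unknown:
        raise ValueError(f"nodes not in network: {sorted(unknown)[:5]}")
    if remove_set >= nodes:
        raise ValueError("cannot remove every node")
    before = cohesion_stats(net)
    after = cohesion_stats(net.subgraph(nodes - remove_set).copy())

    baseline = None
    if baseline_repeats > 0:
        rng = np.random.default_rng(seed)
        pool = sorted(nodes - remove_set)
        diams, geos, comps = [], [], []
        for _ in range(baseline_repeats):
            drop = set(rng.choice(pool, size=len(remove_set), replace=False))
            stats_r = cohesion_stats(net.subgraph(nodes - drop).copy())
            diams.append(stats_r["diameter"])
            geos.append(stats_r["mean_geodesic"])
            comps.append(stats_r["n_components"])
        baseline = {
            "repeats": baseline_repeats,
            "n_removed": len(remove_set),
            "diameter_mean": float(np.mean(diams)),
            "diameter_sd": float(np.std(diams, ddof=1)) if baseline_repeats > 1 else 0.0,
            "mean_geodesic_mean": float(np.mean(geos)),
            "mean_geodesic_sd": float(np.std(geos, ddof=1)) if baseline_repeats > 1 else 0.0,
            "n_components_mean": float(np.mean(comps)),
        }
    return CohesionReport(
        before=before, after=after, removed=sorted(remove_set), baseline=baseline
    )
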