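"""Spearman co-expression networks.

Pairwise Spearman correlations over samples are tested with the
t-approximation, BH-corrected over the unique gene pairs, and
thresholded (default: q < 0.001 and |rho| >= 0.8) into an undirected
simple graph whose edges carry rho, p, and q. Topology summaries
(density, degree histogram, components) support the downstream
community, hub, and differential-network stages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CorrMatrix",
    "NetworkSummary",
    "spearman_rho",
    "corr_test",
    "correlation_matrix",
    "build_network",
    "network_summary",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks
    (average ranks on ties).

    Raises
    ------
    ValueError
        For length mismatch, n < 3, or a zero-variance input (rank
        correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(np.clip(rho, -1.0, 1.0))


def corr_test(rho: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via the t-approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n - 2 df; |rho| = 1
    maps to p = 0."""
    if n < 4:
        raise ValueError("need n >= 4 samples for the correlation test")
    if abs(rho) > 1 + 1e-12:
        raise ValueError("|rho| must be <= 1")
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def exact_spearman_pvalue(rho: float, n: int, n_perm: int | None = None, seed: int = 0) -> float:
    """Two-sided permutation p for the Spearman coefficient at small n,
    an alternative to the t-approximation.

    Exact by full enumeration of untied rank permutations for n <= 8;
    larger n needs an explicit Monte-Carlo permutation count ``n_perm``
    (p then includes the +1 correction).
    """
    from itertools import permutations

    if n_perm is None:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8; pass n_perm")
        perms = np.array(list(permutations(range(n))), dtype=float)
        base = np.arange(n, dtype=float)
        d2 = ((perms - base) ** 2).sum(axis=1)
        rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        return float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
    rng = np.random.default_rng(seed)
    base = np.arange(n, dtype=float)
    d2 = np.array(
        [((rng.permutation(n) - base) ** 2).sum() for _ in range(n_perm)]
    )
    rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float((1 + (np.abs(rhos) >= abs(rho) - 1e-12).sum()) / (n_perm + 1))


@dataclass
class CorrMatrix:
    """All-pairs Spearman correlations with per-pair p and BH q.

    q is computed over the off-diagonal upper triangle only (each
    unordered pair tested once) and mirrored; the diagonal is rho = 1,
    p = q = 0 by convention.
    """

    genes: list[str]
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_samples: int


def correlation_matrix(expr: pd.DataFrame, genes=None) -> CorrMatrix:
    """Spearman correlation matrix over samples (columns) for the given
    genes (rows of ``expr``).

    Constant-expression genes are dropped with a logged warning rather
    than silently propagating undefined correlations.
    """
    if genes is not None:
        gene_list = [g.strip() if isinstance(g, str) else g for g in genes]
        missing = [g for g in gene_list if g not in expr.index]
        if missing:
            raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
        expr = expr.loc[gene_list]
    n = expr.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for correlation testing")
    values = expr.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        dropped = [g for g, c in zip(expr.index, constant) if c]
        logger.warning(
            "dropping %d constant-expression gene(s): %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
        expr = expr.loc[~constant]
        values = expr.to_numpy(dtype=float)
    gene_ids = list(expr.index)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-15] = 0.0
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(len(gene_ids), k=1)
    q = np.zeros_like(p)
    if iu[0].size:
        q_upper = bh_adjust(p[iu])
        q[iu] = q_upper
        q[(iu[1], iu[0])] = q_upper
    return CorrMatrix(gene_ids, rho, p, q, n)


def build_network(
    corr: CorrMatrix,
    fdr_max: float = 0.001,
    rho_min: float = 0.8,
    use_abs: bool = True,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected gene network.

    An edge joins genes i, j iff ``q < fdr_max`` and ``|rho| >= rho_min``
    (signed rho when ``use_abs=False``). Isolated genes remain as nodes.
    Thresholds are recorded as graph attributes.
    """
    if fdr_max <= 0 or rho_min <= -1:
        raise ValueError("invalid thresholds")
    g = nx.Graph(fdr_max=fdr_max, rho_min=rho_min, use_abs=use_abs, n_samples=corr.n_samples)
    g.add_nodes_from(corr.genes)
    strength = np.abs(corr.rho) if use_abs else corr.rho
    iu = np.triu_indices(len(corr.genes), k=1)
    keep = (corr.q[iu] < fdr_max) & (strength[iu] >= rho_min)
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(
            corr.genes[i],
            corr.genes[j],
            rho=float(corr.rho[i, j]),
            p=float(corr.p[i, j]),
            q=float(corr.q[i, j]),
        )
    return g


@dataclass
class NetworkSummary:
    """Topology summary: density is 2m / (n(n-1))."""

    n_nodes: int
    n_edges: int
    edge_density: float
    degree_bin_edges: list[float]
    degree_counts: list[int]
    n_components: int
    largest_component: int

    def to_dict(self) -> dict:
        return asdict(self)


def _adjacency(net: nx.Graph):
    nodes = list(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for u, v in net.edges:
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    import scipy.sparse as sp

    n = len(nodes)
    data = np.ones(len(rows))
    return nodes, sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def network_summary(net: nx.Graph, n_bins: int = 10) -> NetworkSummary:
    """Node/edge counts, edge density, degree histogram with explicit bin
    edges, and connected-component sizes."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("summary needs at least 2 nodes")
    m = net.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    degrees = np.array([d for _, d in net.degree()])
    hi = max(int(degrees.max()), 1)
    edges = np.linspace(0, hi, n_bins + 1) if hi >= n_bins else np.arange(hi + 2)
    counts, edges = np.histogram(degrees, bins=edges)
    _, adj = _adjacency(net)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        edge_density=float(density),
        degree_bin_edges=[float(e) for e in edges],
        degree_counts=[int(c) for c in counts],
        n_components=int(n_comp),
        largest_component=int(sizes.max()),
    )
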