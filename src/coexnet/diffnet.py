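"""Differential network analysis.

Two networks built on the *same* gene set — one from control samples,
one from stimulated samples, with identical thresholds — are compared
purely by topology: edge counts and density, edge-set Jaccard overlap,
degree histograms on shared bins, and the empirical distribution of
retained correlation strengths |rho| (ECDF on a fixed grid plus a
two-sample KS statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import GeneSet
from .network import correlation_matrix, build_network

__all__ = ["NetworkComparison", "matched_networks", "compare_networks"]


@dataclass
class NetworkComparison:
    """Topology comparison of two networks on a common node set."""

    labels: tuple[str, str]
    n_nodes: int
    n_edges: tuple[int, int]
    density: tuple[float, float]
    shared_nodes: int
    edge_jaccard: float
    degree_bin_edges: list[float]
    degree_counts: tuple[list[int], list[int]]
    weight_grid: list[float]
    weight_cdf: tuple[list[float], list[float]]
    min_abs_rho: tuple[float, float]
    ks_statistic: float

    def to_dict(self) -> dict:
        return asdict(self)


def matched_networks(
    genes,
    expr_control: pd.DataFrame,
    expr_treat: pd.DataFrame,
    fdr_max: float = 0.001,
    rho_min: float = 0.8,
    use_abs: bool = True,
) -> tuple[nx.Graph, nx.Graph]:
    """Control and stimulus networks over an identical gene set.

    Each network is inferred from its own samples with the same
    thresholds, so differences in edges reflect the condition, not the
    gene list. Raises if any gene is absent from either matrix.
    """
    gene_list = sorted(genes.genes if isinstance(genes, GeneSet) else set(genes))
    for label, expr in (("control", expr_control), ("treatment", expr_treat)):
        missing = [g for g in gene_list if g not in expr.index]
        if missing:
            raise ValueError(f"genes missing from {label} matrix: {missing[:5]}")
    nets = []
    for expr in (expr_control, expr_treat):
        corr = correlation_matrix(expr, gene_list)
        net = build_network(corr, fdr_max=fdr_max, rho_min=rho_min, use_abs=use_abs)
        # genes dropped for constant expression stay as isolated nodes
        net.add_nodes_from(gene_list)
        nets.append(net)
    return nets[0], nets[1]


def _edge_weights(net: nx.Graph) -> np.ndarray:
    return np.array([abs(d.get("rho", 1.0)) for _, _, d in net.edges(data=True)])


def compare_networks(
    a: nx.Graph,
    b: nx.Graph,
    labels: tuple[str, str] = ("control", "treatment"),
    weight_grid=None,
) -> NetworkComparison:
    """Symmetric (up to label order) topology comparison; requires the
    same node set.

    Degree histograms share bin edges computed from the pooled degree
    range; |rho| ECDFs are sampled on a fixed grid (default 0.80..1.00,
    step 0.01).
    """
    if set(a.nodes) != set(b.nodes):
        raise ValueError("networks must share one node set")
    n = a.number_of_nodes()
    ea = {frozenset(e) for e in a.edges}
    eb = {frozenset(e) for e in b.edges}
    union = ea | eb
    jaccard = len(ea & eb) / len(union) if union else 1.0

    deg_a = np.array([d for _, d in a.degree()])
    deg_b = np.array([d for _, d in b.degree()])
    hi = max(int(deg_a.max(initial=0)), int(deg_b.max(initial=0)), 1)
    n_bins = min(10, hi + 1)
    bin_edges = np.linspace(0, hi, n_bins + 1)
    counts_a, _ = np.histogram(deg_a, bins=bin_edges)
    counts_b, _ = np.histogram(deg_b, bins=bin_edges)

    if weight_grid is None:
        lo = min(float(a.graph.get("rho_min", 0.8)), float(b.graph.get("rho_min", 0.8)))
        weight_grid = np.round(np.arange(lo, 1.0 + 1e-9, 0.01), 4)
    weight_grid = np.asarray(weight_grid, dtype=float)
    wa, wb = _edge_weights(a), _edge_weights(b)
    cdf_a = [float((wa <= g).mean()) if wa.size else 1.0 for g in weight_grid]
    cdf_b = [float((wb <= g).mean()) if wb.size else 1.0 for g in weight_grid]
    ks = (
        float(stats.ks_2samp(wa, wb).statistic) if wa.size and wb.size else float(wa.size != wb.size)
    )
    density = lambda g: 2.0 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return NetworkComparison(
        labels=labels,
        n_nodes=n,
        n_edges=(a.number_of_edges(), b.number_of_edges()),
        density=(density(a), density(b)),
        shared_nodes=n,
        edge_jaccard=float(jaccard),
        degree_bin_edges=[float(e) for e in bin_edges],
        degree_counts=([int(c) for c in counts_a], [int(c) for c in counts_b]),
        weight_grid=[float(g) for g in weight_grid],
        weight_cdf=(cdf_a, cdf_b),
        min_abs_rho=(
            float(wa.min()) if wa.size else float("nan"),
            float(wb.min()) if wb.size else float("nan"),
        ),
        ks_statistic=ks,
    )
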