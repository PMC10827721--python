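"""Centrality computation, composite hub scoring, per-community
selection, and removal-based robustness analysis."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet.communities import CommunityPartition, best_partition, walktrap_dendrogram
from coexnet.diffexpr import GeneSet, log_cpm, tmm_factors
from coexnet.hubs import (
    centralities,
    cohesion_stats,
    hub_scores,
    removal_report,
    select_hubs,
)
from coexnet.network import build_network, correlation_matrix
from coexnet.synthetic import GeneratorParams, make_design, simulate_experiment


class TestCentralities:
    def test_star_hand_values(self):
        # K1,4: center closeness 1, leaf 4/7; authority center/leaf = sqrt(4)
        g = nx.star_graph(4)
        c = centralities(g)
        assert c.loc[0, "closeness"] == pytest.approx(1.0)
        assert c.loc[1, "closeness"] == pytest.approx(4 / 7)
        assert c.loc[0, "authority"] / c.loc[1, "authority"] == pytest.approx(2.0, abs=1e-6)
        assert c.loc[0, "degree"] == 4

    def test_vertex_transitive_graph_uniform(self):
        c = centralities(nx.cycle_graph(6))
        for col in ("degree", "closeness", "authority"):
            assert c[col].nunique() == 1

    def test_isolated_node_zeroes(self):
        g = nx.path_graph(3)
        g.add_node("iso")
        c = centralities(g)
        assert c.loc["iso", "closeness"] == 0.0
        assert c.loc["iso", "degree"] == 0

    @pytest.mark.parametrize("seed", [1, 5])
    def test_authority_matches_dense_eigendecomposition(self, seed):
        g = nx.gnp_random_graph(50, 0.12, seed=seed)
        c = centralities(g)
        a = nx.to_numpy_array(g, nodelist=list(g.nodes))
        w, v = np.linalg.eigh(a)
        principal = np.abs(v[:, np.argmax(w)])
        principal /= principal.max()
        assert np.max(np.abs(c["authority"].to_numpy() - principal)) < 1e-8

    @pytest.mark.parametrize("seed", [2, 7])
    def test_closeness_diameter_match_floyd_warshall(self, seed):
        g = nx.gnp_random_graph(40, 0.1, seed=seed)
        nodes, = [list(g.nodes)]
        from scipy.sparse.csgraph import floyd_warshall
        import scipy.sparse as sp

        a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr")
        dist = floyd_warshall(sp.csr_matrix(a), directed=False, unweighted=True)
        c = centralities(g)
        for i, v in enumerate(nodes):
            finite = np.isfinite(dist[i])
            n_reach = finite.sum() - 1
            expected = n_reach / dist[i][finite].sum() if n_reach else 0.0
            assert c.loc[v, "closeness"] == pytest.approx(expected)
        stats = cohesion_stats(g)
        offdiag = dist[np.isfinite(dist)]
        assert stats["diameter"] == int(offdiag.max())


class TestHubScores:
    def test_isolated_node_score_zero(self):
        g = nx.path_graph(3)
        g.add_node("iso")
        scores = hub_scores(centralities(g))
        assert scores.loc["iso", "score"] == 0.0

    def test_dominant_node_ranked_first(self):
        scores = hub_scores(centralities(nx.star_graph(5)))
        assert scores.index[0] == 0
        assert scores.loc[0, "rank"] == 1

    def test_path_ends_score_below_middles(self):
        scores = hub_scores(centralities(nx.path_graph(4)))
        assert scores.loc[0, "score"] < scores.loc[1, "score"]
        assert scores.loc[3, "score"] < scores.loc[2, "score"]

    def test_tie_break_by_gene_id(self):
        g = nx.Graph([("b", "a"), ("d", "c")])  # two symmetric edges
        scores = hub_scores(centralities(g))
        assert list(scores.index) == sorted(scores.index, key=lambda s: (-scores.loc[s, "score"], s))


class TestSelectHubs:
    @staticmethod
    def _setup(sizes, k):
        labels = {}
        g = nx.Graph()
        node = 0
        for c, size in enumerate(sizes):
            members = [f"g{node + i:04d}" for i in range(size)]
            node += size
            g.add_edges_from(
                (members[i], members[(i + 1) % size]) for i in range(size)
            )
            for mbr in members:
                labels[mbr] = c
        part = CommunityPartition(labels, q=0.5)
        scores = hub_scores(centralities(g))
        return part, scores

    def test_three_communities_give_150(self):
        part, scores = self._setup([60, 70, 80], k=50)
        table = select_hubs(part, scores, k=50)
        assert len(table) == 150

    def test_small_community_clamped(self):
        part, scores = self._setup([30], k=50)
        table = select_hubs(part, scores, k=50)
        assert len(table) == 30

    def test_k_one_is_argmax(self):
        part, scores = self._setup([10, 10], k=1)
        table = select_hubs(part, scores, k=1)
        assert len(table) == 2

    def test_unknown_community_rejected(self):
        part, scores = self._setup([10], k=5)
        with pytest.raises(ValueError, match="unknown community"):
            select_hubs(part, scores, k=5, communities=["nope"])


class TestRemovalReport:
    def test_remove_leaf_from_star(self):
        g = nx.star_graph(5)
        rep = removal_report(g, {1})
        assert rep.after["diameter"] == 2
        assert rep.after["n_components"] == 1
        assert rep.after["n_nodes"] == rep.before["n_nodes"] - 1

    def test_remove_star_center_fragments(self):
        g = nx.star_graph(5)
        rep = removal_report(g, {0})
        assert rep.after["n_components"] == 5
        assert rep.after["n_edges"] == 0
        assert rep.after["mean_geodesic"] == 0.0
        assert rep.after["unreachable_fraction"] == 1.0

    def test_empty_removal_identity(self):
        g = nx.gnp_random_graph(15, 0.3, seed=1)
        rep = removal_report(g, set())
        assert rep.before == rep.after

    def test_remove_all_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            removal_report(g, {0, 1, 2})

    def test_baseline_distribution_reported(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        rep = removal_report(g, {0, 1}, baseline_repeats=5, seed=0)
        assert rep.baseline["repeats"] == 5
        assert rep.baseline["n_removed"] == 2
        assert rep.baseline["mean_geodesic_mean"] > 0

    def test_hub_attack_beats_random_on_scale_free_graph(self):
        # preferential-attachment hubs hold the graph together: their
        # removal lengthens geodesics more than random removals
        g = nx.barabasi_albert_graph(300, 2, seed=7)
        scores = hub_scores(centralities(g))
        top10 = set(scores.index[:10])
        rep = removal_report(g, top10, baseline_repeats=20, seed=11)
        assert rep.after["mean_geodesic"] > rep.baseline["mean_geodesic_mean"]
        assert rep.after["mean_geodesic"] > rep.before["mean_geodesic"]


class TestPlantedHubRecovery:
    def test_planted_hubs_surface_in_top_ranks(self):
        # hubs planted with loading 0.95 inside 0.6-loading modules are
        # recovered in the per-module top-2k of the composite score
        design = make_design(5)  # 45 samples
        params = GeneratorParams(
            n_genes=200,
            module_sizes=(40, 40, 40),
            module_loading=0.6,
            hub_per_module=5,
            hub_loading=0.95,
            de_fraction=0.0,
            dispersion=0.1,
            seed=3,
        )
        cm, truth = simulate_experiment(design, params)
        net = build_network(correlation_matrix(log_cpm(cm, tmm_factors(cm))))
        part = best_partition(walktrap_dendrogram(net))
        scores = hub_scores(centralities(net))
        hits = total = 0
        for module, hubs in truth.hub_genes.items():
            members = [g for g, m in truth.module_of.items() if m == module]
            comms = [part.labels[g] for g in members if g in part.labels]
            majority = max(set(comms), key=comms.count)
            table = select_hubs(part, scores, k=2 * len(hubs), communities=[majority])
            hits += len(set(table["gene_id"]) & set(hubs))
            total += len(hubs)
        assert hits / total >= 0.70
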