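import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from aridnet.errors import ConfigurationError
from aridnet.io import OtuTable
from aridnet.network import (build_network, class_summary, deconvolve,
                             filter_rare, graph_stats, network_pipeline,
                             node_environment, node_metric_env_correlation,
                             rmt_threshold, sample_level_stats,
                             spearman_matrix)


class TestFilterRare:
    def test_zero_fraction_keeps_everything(self, toy_table):
        out = filter_rare(toy_table, 0.0)
        assert out.otu_ids == toy_table.otu_ids

    def test_abundance_cut_arithmetic(self):
        counts = pd.DataFrame([[1, 10, 100, 1000, 10000]], index=["s"],
                              columns=list("abcde"))
        out = filter_rare(OtuTable(counts), 1e-4)
        # grand total 11111 -> cut 1.1111: only the singleton drops
        assert out.otu_ids == list("bcde")

    def test_invalid_fraction(self, toy_table):
        with pytest.raises(ConfigurationError):
            filter_rare(toy_table, 1.5)


class TestSpearmanMatrix:
    def test_identical_vectors_correlate_fully(self):
        counts = pd.DataFrame(
            [[1, 1, 9], [5, 5, 2], [9, 9, 1], [2, 2, 8]],
            index=list("wxyz"), columns=["a", "b", "c"])
        R, P = spearman_matrix(OtuTable(counts))
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] < 0

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 50, size=(8, 6)),
                              index=[f"s{i}" for i in range(8)],
                              columns=list("abcdef"))
        table = OtuTable(counts)
        R, P = spearman_matrix(table)
        ra = table.relative_abundance().to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            res = scipy.stats.spearmanr(ra[:, i], ra[:, j])
            assert R[i, j] == pytest.approx(res.statistic, abs=1e-10)
            assert P[i, j] == pytest.approx(res.pvalue, abs=1e-10)

    def test_constant_otu_flagged_not_fatal(self):
        counts = pd.DataFrame(
            [[5, 1, 0], [5, 2, 3], [5, 3, 1], [5, 4, 2]],
            index=list("wxyz"), columns=["const", "a", "b"])
        # 'const' has constant counts but varying relative abundance;
        # build a truly constant RA column instead
        counts["const"] = [10, 20, 30, 40]
        counts["a"] = [10, 20, 30, 40]
        counts["b"] = [0, 0, 0, 0]
        R, P = spearman_matrix(OtuTable(counts))
        assert R[2, 0] == 0.0
        assert P[2, 0] == 1.0


class TestDeconvolve:
    def test_zero_matrix(self):
        out = deconvolve(np.zeros((4, 4)))
        assert np.allclose(out, 0.0)

    def test_transitive_edge_suppressed_on_chain(self):
        # direct AB = BC = 0.9; the transitive AC = 0.81 must come out
        # weaker than both direct edges
        R = np.array([[1.0, 0.9, 0.81],
                      [0.9, 1.0, 0.9],
                      [0.81, 0.9, 1.0]])
        D = deconvolve(R)
        assert D[0, 2] < D[0, 1]
        assert D[0, 2] < D[1, 2]

    def test_output_symmetric(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(20, 20))
        R = (M + M.T) / 2
        D = deconvolve(R)
        assert np.max(np.abs(D - D.T)) < 1e-10

    def test_inverse_transform_recovers_scaled_spectrum(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(-0.5, 0.5, size=(15, 15))
        R = (M + M.T) / 2
        np.fill_diagonal(R, 1.0)
        D, alpha = deconvolve(R, return_alpha=True)
        G = R.copy()
        np.fill_diagonal(G, 0.0)
        lam_d = np.linalg.eigvalsh(D)
        recovered = lam_d / (1.0 - lam_d)
        expected = alpha * np.linalg.eigvalsh(G)
        assert np.allclose(np.sort(recovered), np.sort(expected),
                           atol=1e-8)

    def test_asymmetric_input_raises(self):
        with pytest.raises(ConfigurationError):
            deconvolve(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestRmtThreshold:
    def test_noise_matrix_threshold_above_noise_quantile(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 60))
        R = scipy.stats.spearmanr(X).statistic
        iu = np.triu_indices(60, 1)
        q95 = np.quantile(np.abs(R[iu]), 0.95)
        thr, diag = rmt_threshold(
            R, grid=np.round(np.arange(0.10, 1.0, 0.02), 2))
        assert thr > q95
        # at low cutoffs the noise bulk must not look Poisson
        low = diag[diag.threshold <= 0.14].dropna()
        assert (low["p_poisson"] < 0.05).all()

    def test_planted_blocks_bound_the_threshold(self):
        rng = np.random.default_rng(3)
        n, b = 100, 25
        R = rng.uniform(-0.4, 0.4, size=(n, n))
        R = (R + R.T) / 2
        for k in range(4):
            s = slice(k * b, (k + 1) * b)
            blk = rng.uniform(0.85, 0.95, size=(b, b))
            R[s, s] = (blk + blk.T) / 2
        np.fill_diagonal(R, 1.0)
        thr, _ = rmt_threshold(R)
        assert 0.5 <= thr < 0.9

    def test_small_matrix_raises(self):
        with pytest.raises(ConfigurationError):
            rmt_threshold(np.eye(10))


class TestBuildNetwork:
    def _matrices(self, n, strong_pairs):
        R = np.zeros((n, n))
        P = np.ones((n, n))
        np.fill_diagonal(R, 1.0)
        np.fill_diagonal(P, 0.0)
        for i, j, r in strong_pairs:
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = 1e-8
        D = R.copy()
        np.fill_diagonal(D, 0.0)
        return R, P, D

    def test_single_passing_pair(self):
        R, P, D = self._matrices(5, [(0, 1, 0.95)])
        net = build_network(R, P, D, list("abcde"), threshold=0.8)
        assert net.n_nodes == 2
        assert net.n_edges == 1
        assert net.fraction_positive == 1.0

    def test_threshold_one_gives_empty_network(self):
        R, P, D = self._matrices(5, [(0, 1, 0.95)])
        net = build_network(R, P, D, list("abcde"), threshold=1.0)
        assert net.n_edges == 0

    def test_every_edge_satisfies_all_rules(self, small_block_dataset):
        dataset, _ = small_block_dataset
        filtered = filter_rare(dataset.table)
        R, P = spearman_matrix(filtered)
        D = deconvolve(R)
        net = build_network(R, P, D, filtered.otu_ids, threshold=0.7)
        idx = {o: i for i, o in enumerate(filtered.otu_ids)}
        for a, b, attrs in net.graph.edges(data=True):
            assert abs(attrs["rs"]) >= 0.7
            assert attrs["q"] <= net.q_cutoff
            assert attrs["deconvolved"] > 0
            assert attrs["sign"] == np.sign(attrs["rs"])
            assert attrs["rs"] == pytest.approx(R[idx[a], idx[b]])

    def test_negative_deconvolved_weight_blocks_edge(self):
        R, P, D = self._matrices(5, [(0, 1, 0.95)])
        D[0, 1] = D[1, 0] = -0.2
        net = build_network(R, P, D, list("abcde"), threshold=0.8)
        assert net.n_edges == 0


class TestGraphStats:
    def test_star_centralization_is_one(self):
        stats = graph_stats(nx.star_graph(4))  # 5 nodes
        assert stats["betweenness_centralization"] == pytest.approx(1.0)

    def test_complete_graph(self):
        stats = graph_stats(nx.complete_graph(4))
        assert stats["avg_path_length"] == pytest.approx(1.0)
        assert stats["betweenness_centralization"] == pytest.approx(0.0)
        assert stats["degree"] == pytest.approx(3.0)

    def test_path_graph_average_path_length(self):
        # P3: pairs (a,b), (b,c) at distance 1 and (a,c) at 2 -> 4/3
        stats = graph_stats(nx.path_graph(3))
        assert stats["avg_path_length"] == pytest.approx(4.0 / 3.0)

    def test_disconnected_reachable_pairs_only(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        stats = graph_stats(g)
        assert stats["avg_path_length"] == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = nx.gnp_random_graph(7, 0.4, seed=int(rng.integers(1000)))
            stats = graph_stats(g)
            # brute-force shortest paths via matrix powers-free BFS
            total, pairs = 0, 0
            for u, v in itertools.combinations(g.nodes, 2):
                try:
                    d = nx.shortest_path_length(g, u, v)
                    total += d
                    pairs += 1
                except nx.NetworkXNoPath:
                    pass
            expected = total / pairs if pairs else 0.0
            assert stats["avg_path_length"] == pytest.approx(expected)
            assert stats["edge_count"] == g.number_of_edges()


class TestSampleLevelStats:
    def _net_from_graph(self, g):
        from aridnet.network import CooccurrenceNetwork
        return CooccurrenceNetwork(graph=g, threshold_used=0.8,
                                   q_cutoff=0.01, fraction_positive=1.0)

    def test_induced_star(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {i: f"o{i}" for i in g.nodes})
        net = self._net_from_graph(g)
        counts = pd.DataFrame([[1] * 5], index=["s"],
                              columns=[f"o{i}" for i in range(5)])
        stats = sample_level_stats(net, OtuTable(counts))
        row = stats.loc["s"]
        assert row["size"] == 5
        assert row["betweenness_centralization"] == pytest.approx(1.0)
        assert row["edge_count"] == 4

    def test_absent_nodes_excluded(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"o{i}" for i in g.nodes})
        net = self._net_from_graph(g)
        counts = pd.DataFrame([[1, 1, 0, 0]], index=["s"],
                              columns=[f"o{i}" for i in range(4)])
        stats = sample_level_stats(net, OtuTable(counts))
        assert stats.loc["s", "size"] == 2
        assert stats.loc["s", "edge_count"] == 1


class TestNodeEnvironment:
    def test_mean_rh_over_occupied_samples(self, toy_table):
        import networkx as nx
        from aridnet.network import CooccurrenceNetwork
        g = nx.Graph([("A", "C")])
        net = CooccurrenceNetwork(graph=g, threshold_used=0.8,
                                  q_cutoff=0.01, fraction_positive=1.0)
        meta = pd.DataFrame({"AvgSoilRH": [10.0, 30.0, 50.0]},
                            index=["s1", "s2", "s3"])
        node_environment(net, toy_table, meta)
        # OTU A occurs in s1 and s2 -> mean 20
        assert net.graph.nodes["A"]["mean_rh"] == pytest.approx(20.0)
        # OTU C occurs in s1 and s3 -> mean 30
        assert net.graph.nodes["C"]["mean_rh"] == pytest.approx(30.0)


class TestClassSummary:
    def test_single_sample_per_class_passthrough(self):
        stats = pd.DataFrame(
            {"size": [10.0, 5.0, 2.0], "degree": [3.0, 2.0, 1.0],
             "betweenness": [1.0, 1.0, 0.0], "edge_count": [9.0, 4.0, 1.0],
             "avg_path_length": [1.5, 2.0, 1.0],
             "betweenness_centralization": [0.1, 0.2, 0.0]},
            index=["a1", "m1", "h1"])
        classes = pd.Series({"a1": "arid", "m1": "margin",
                             "h1": "hyperarid"})
        out = class_summary(stats, classes)
        assert out.loc["arid", "size"] == 10.0
        assert list(out.columns) == ["size", "degree", "betweenness",
                                     "edge_count", "avg_path_length",
                                     "betweenness_centralization"]

    def test_median_midpoint_convention(self):
        stats = pd.DataFrame(
            {"size": [1.0, 2.0, 9.0], "degree": [0, 0, 0],
             "betweenness": [0, 0, 0], "edge_count": [1.0, 2.0, 9.0],
             "avg_path_length": [0, 0, 0],
             "betweenness_centralization": [0, 0, 0]},
            index=["a1", "a2", "a3"], dtype=float)
        classes = pd.Series("arid", index=stats.index)
        out = class_summary(stats, classes)
        assert out.loc["arid", "edge_count"] == 2.0


class TestMetricEnvCorrelation:
    def test_reports_exactly_four_pairs(self, small_block_dataset):
        dataset, _ = small_block_dataset
        net = network_pipeline(dataset.table, threshold=0.75)
        node_environment(net, dataset.table, dataset.metadata)
        stats = sample_level_stats(net, dataset.table)
        corr = node_metric_env_correlation(net, stats, dataset.metadata)
        assert list(corr["metric"]) == ["degree", "betweenness",
                                       "edge_count", "size"]
        assert set(corr["level"]) == {"node", "sample"}

    def test_degenerate_rh_flagged_not_fatal(self):
        import networkx as nx
        from aridnet.network import CooccurrenceNetwork
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {i: f"o{i}" for i in g.nodes})
        for n in g.nodes:
            g.nodes[n]["mean_rh"] = 15.0
        net = CooccurrenceNetwork(graph=g, threshold_used=0.8,
                                  q_cutoff=0.01, fraction_positive=1.0)
        stats = pd.DataFrame(
            {"size": [3.0], "degree": [1.3], "betweenness": [0.3],
             "edge_count": [2.0], "avg_path_length": [1.3],
             "betweenness_centralization": [0.5]}, index=["s"])
        meta = pd.DataFrame({"AvgSoilRH": [15.0]}, index=["s"])
        corr = node_metric_env_correlation(net, stats, meta)
        assert corr["rs"].isna().all()
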