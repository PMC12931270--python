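import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bpdnet import (CoNetwork, build_network, downsample_groups, generate_cohort,
                    keystone_scores, threshold_sensitivity, topology)
from bpdnet.netbuild import TopologyReport, jaccard, mean_relative_abundance
from bpdnet.sparcc import CorrelationResult
from bpdnet.synth import CohortConfig


def _net_from_graph(g: nx.Graph, threshold: float = 0.3) -> CoNetwork:
    for u, v, d in g.edges(data=True):
        d.setdefault("r", 0.5)
    return CoNetwork(g, threshold=threshold)


def _cor(ids, r, p=None) -> CorrelationResult:
    return CorrelationResult(list(ids), np.asarray(r, dtype=float),
                             None if p is None else np.asarray(p, dtype=float))


class TestDownsampleGroups:
    def test_all_groups_reach_smallest_size(self, small_cohort):
        table, _, meta = small_cohort
        groups = downsample_groups(table, meta, seed=0)
        assert {g: t.n_samples for g, t in groups.items()} == {
            "non": 5, "I": 5, "II": 5, "III": 5}

    def test_group_at_target_unchanged(self, small_cohort):
        table, _, meta = small_cohort
        groups = downsample_groups(table, meta, seed=0)
        assert set(groups["III"].sample_ids) == set(meta.samples_in_group("III"))

    def test_deterministic_under_seed(self, small_cohort):
        table, _, meta = small_cohort
        a = downsample_groups(table, meta, seed=4)
        b = downsample_groups(table, meta, seed=4)
        assert all(a[g].sample_ids == b[g].sample_ids for g in a)

    def test_oversized_target_names_group(self, small_cohort):
        table, _, meta = small_cohort
        with pytest.raises(ValueError, match="III"):
            downsample_groups(table, meta, target_n=6, seed=0)


class TestBuildNetwork:
    def test_threshold_strict_boundary(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.3
        net = build_network(_cor(["a", "b"], r), threshold=0.3, alpha=1.0)
        assert net.n_edges == 0

    def test_significance_conjunction(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.5
        p = np.full((2, 2), 0.2)
        net = build_network(_cor(["a", "b"], r, p), threshold=0.3, alpha=0.05)
        assert net.n_edges == 0

    def test_triangle_with_isolated_node_dropped(self):
        ids = ["a", "b", "c", "d"]
        r = np.eye(4)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            r[i, j] = r[j, i] = 0.6
        r[0, 3] = r[3, 0] = 0.9   # strong but not significant
        p = np.full((4, 4), 0.01)
        p[0, 3] = p[3, 0] = 0.5
        net = build_network(_cor(ids, r, p), threshold=0.3, alpha=0.05)
        assert net.n_nodes == 3 and net.n_edges == 3
        assert "d" not in net.graph


class TestTopology:
    def test_degree_density_identities_match_published_counts(self):
        """Average degree and density recomputed from (N, E) agree with the
        printed per-group profiles to 2 d.p."""
        cases = [(42, 34, 1.62, 0.04), (153, 445, 5.82, 0.04),
                 (159, 2317, 29.14, 0.18), (29, 20, 1.38, 0.05)]
        for n, e, avg_deg, dens in cases:
            g = nx.gnm_random_graph(n, e, seed=1)
            rep = topology(_net_from_graph(g), metrics={"average_degree"})
            assert rep.average_degree == pytest.approx(2 * e / n)
            assert round(rep.average_degree, 2) == avg_deg
            assert round(rep.density, 2) == dens

    def test_complete_graph_closed_forms(self):
        rep = topology(_net_from_graph(nx.complete_graph(5)))
        assert rep.density == 1
        assert rep.clustering_coefficient == 1
        assert rep.average_path_length == 1
        assert rep.diameter == 1

    def test_star_graph_extremes(self):
        rep = topology(_net_from_graph(nx.star_graph(5)))
        assert rep.clustering_coefficient == 0
        assert rep.betweenness_centralization == pytest.approx(1.0)
        assert rep.closeness_centralization == pytest.approx(1.0)

    @pytest.mark.parametrize("graph", [nx.cycle_graph(7), nx.complete_graph(6)])
    def test_centralization_zero_for_vertex_transitive(self, graph):
        rep = topology(_net_from_graph(graph))
        assert rep.betweenness_centralization == pytest.approx(0.0, abs=1e-9)
        assert rep.closeness_centralization == pytest.approx(0.0, abs=1e-9)
        assert rep.eigenvector_centralization == pytest.approx(0.0, abs=1e-6)

    def test_empty_network_flagged_null(self):
        rep = topology(CoNetwork(nx.Graph(), threshold=0.3))
        assert rep.nodes == 0 and rep.edges == 0
        assert math.isnan(rep.average_path_length)

    def test_path_metrics_match_floyd_warshall_oracle(self, rng):
        """Hop-count path length, diameter and betweenness agree exactly with
        a brute-force Floyd-Warshall + path-counting oracle."""
        for trial in range(12):
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1 << 16)))
            rep = topology(_net_from_graph(g),
                           metrics={"average_path_length", "diameter"})
            dist, sigma = _floyd_warshall_with_counts(g)
            finite = [dist[i][j] for i in range(n) for j in range(n)
                      if i != j and not math.isinf(dist[i][j])]
            if finite:
                assert rep.average_path_length == pytest.approx(np.mean(finite))
                assert rep.diameter == max(finite)
            betw = nx.betweenness_centrality(g, normalized=False)
            oracle = _betweenness_oracle(g, dist, sigma)
            for v in g.nodes:
                assert betw[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_dissimilarity_weighted_paths(self):
        g = nx.Graph()
        g.add_edge("a", "b", r=0.9)   # length 0.1
        g.add_edge("b", "c", r=0.5)   # length 0.5
        g.add_edge("a", "c", r=0.31)  # length 0.69 > 0.6 via b
        rep = topology(CoNetwork(g, threshold=0.3),
                       mode="dissimilarity_weighted",
                       metrics={"average_path_length", "diameter"})
        assert rep.diameter == pytest.approx(0.6)

    def test_modularity_at_least_trivial_partition(self, small_cohort):
        g = nx.planted_partition_graph(3, 8, 0.8, 0.05, seed=2)
        rep = topology(_net_from_graph(nx.Graph(g)), metrics={"modularity"})
        assert rep.modularity >= 0  # trivial one-community partition scores 0


def _floyd_warshall_with_counts(g: nx.Graph):
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = [[math.inf] * n for _ in range(n)]
    sigma = [[0] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
        sigma[i][i] = 1
    for u, v in g.edges:
        i, j = idx[u], idx[v]
        dist[i][j] = dist[j][i] = 1
        sigma[i][j] = sigma[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
                    sigma[i][j] = sigma[i][k] * sigma[k][j]
                elif dist[i][k] + dist[k][j] == dist[i][j] and k != i and k != j \
                        and not math.isinf(dist[i][j]):
                    sigma[i][j] += sigma[i][k] * sigma[k][j]
    return dist, sigma


def _betweenness_oracle(g: nx.Graph, dist, sigma):
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    out = {v: 0.0 for v in nodes}
    n = len(nodes)
    for s, t in itertools.combinations(range(n), 2):
        if math.isinf(dist[s][t]) or sigma[s][t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dist[s][v] + dist[v][t] == dist[s][t]:
                out[nodes[v]] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return out


class TestKeystoneScores:
    def test_exact_top_decile_count(self):
        g = nx.gnm_random_graph(29, 60, seed=0)
        scores = keystone_scores(_net_from_graph(g))
        assert scores["keystone_flag"].sum() == 3  # ceil(0.1 * 29)

    def test_dominant_node_always_top(self):
        # hub of a star: max degree/closeness, min... betweenness is high for
        # the hub, so build a clique plus a pendant: clique nodes dominate
        g = nx.complete_graph(6)
        g.add_edge(0, 99)
        scores = keystone_scores(_net_from_graph(g))
        flagged = scores.index[scores["keystone_flag"]]
        assert 99 not in flagged

    def test_matches_independent_recomputation(self):
        """Composite ranking equals a spreadsheet-style recomputation of the
        z-scores and weighted sum on a 10-node graph."""
        g = nx.gnm_random_graph(10, 18, seed=3)
        net = _net_from_graph(g)
        w = (0.4, 0.3, 0.2, 0.1)
        scores = keystone_scores(net, weights=w)

        def z(series):
            arr = np.asarray(series, dtype=float)
            return (arr - arr.mean()) / arr.std(ddof=1)

        deg = pd.Series(dict(g.degree()))
        close = pd.Series(nx.closeness_centrality(g))
        trans = pd.Series(nx.clustering(g))
        betw = pd.Series(nx.betweenness_centrality(g))
        expected = (0.4 * z(deg.sort_index()) + 0.3 * z(close.sort_index())
                    + 0.2 * z(trans.sort_index()) - 0.1 * z(betw.sort_index()))
        assert np.allclose(scores["keystone_composite"].to_numpy(), expected)

    def test_all_zero_weights_rejected(self):
        g = nx.path_graph(5)
        with pytest.raises(ValueError):
            keystone_scores(_net_from_graph(g), weights=(0, 0, 0, 0))

    def test_tie_break_by_degree_then_id(self):
        # two disconnected edges: all composites equal; flag count = 1,
        # tie broken deterministically by id
        g = nx.Graph([("a", "b"), ("c", "d")])
        scores = keystone_scores(_net_from_graph(g))
        assert scores["keystone_flag"].sum() == 1
        assert scores.index[scores["keystone_flag"]][0] == "a"


class TestThresholdSensitivity:
    @pytest.fixture(scope="class")
    def cor(self):
        rng = np.random.default_rng(0)
        d = 30
        r = np.clip(rng.normal(0, 0.25, (d, d)), -0.95, 0.95)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        return _cor([f"t{j}" for j in range(d)], r)

    def test_edge_count_monotone_in_threshold(self, cor):
        out = threshold_sensitivity(cor, thresholds=(0.2, 0.3, 0.4), alpha=1.0)
        edges = out["topology"]["edges"]
        assert edges.loc[0.2] >= edges.loc[0.3] >= edges.loc[0.4]

    def test_self_jaccard_is_one(self, cor):
        out = threshold_sensitivity(cor, thresholds=(0.2, 0.3, 0.4), alpha=1.0)
        for thr in (0.2, 0.3, 0.4):
            if out["keystones"][thr]:
                assert out["keystone_jaccard"].loc[thr, thr] == 1.0

    def test_jaccard_helper(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert math.isnan(jaccard(set(), set()))


def test_mean_relative_abundance_node_attribute(small_cohort):
    table, _, _ = small_cohort
    abund = mean_relative_abundance(table)
    assert sum(abund.values()) == pytest.approx(1.0)
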