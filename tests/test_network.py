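"""Correlation matrices, signed networks, centralities, hubs, communities."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coreactnet as cn
from coreactnet.io import COUNT_COLUMNS

from _oracles import graph_from_nx, max_modularity, modularity, pearson
from conftest import matrix_from_values, random_weighted_graph


def _react_from_values(values, regions, group="G"):
    """Build a reactivation-style frame whose double_pct equals `values`."""
    rows = []
    for a, row in enumerate(np.asarray(values, dtype=float)):
        for r, v in zip(regions, row):
            rows.append((f"a{a}", group, r, np.nan, np.nan, v, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "region", "td_pct", "cfos_pct",
                 "double_pct", "chance_pct", "ratio"],
    )


def _toy_net(edges, sign_mode="positive"):
    g = nx.Graph(sign_mode=sign_mode, group="toy")
    nodes = sorted({n for e in edges for n in e[:2]})
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, r=w)
    return g


class TestCorrelationMatrix:
    def test_perfect_and_anti_correlation(self):
        vals = np.array([[1.0, 1.0, -1.0], [2.0, 2.0, -2.0], [3.0, 3.0, -3.0], [5.0, 5.0, -5.0]])
        react = _react_from_values(vals, ["A", "B", "C"])
        m = cn.correlation_matrix(react, "G", regions=["A", "B", "C"])
        assert m.r.loc["A", "B"] == pytest.approx(1.0)
        assert m.r.loc["A", "C"] == pytest.approx(-1.0)
        assert m.n_cells == 9 and m.n_unique_pairs == 3

    def test_hand_evaluated_pearson(self):
        react = _react_from_values(np.array([[1, 1], [2, 3], [3, 2], [4, 4]]), ["A", "B"])
        m = cn.correlation_matrix(react, "G", regions=["A", "B"])
        assert m.r.loc["A", "B"] == pytest.approx(0.8)
        assert m.r.loc["A", "B"] == pytest.approx(pearson([1, 2, 3, 4], [1, 3, 2, 4]))

    def test_zero_variance_region_left_missing(self):
        vals = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0], [4.0, 7.0]])
        react = _react_from_values(vals, ["A", "B"])
        with pytest.warns(UserWarning, match="zero variance"):
            m = cn.correlation_matrix(react, "G", regions=["A", "B"])
        assert np.isnan(m.r.loc["A", "B"])

    def test_too_few_animals_left_missing(self):
        react = _react_from_values(np.array([[1.0, 2.0], [2.0, 1.0]]), ["A", "B"])
        with pytest.warns(UserWarning, match="fewer than"):
            m = cn.correlation_matrix(react, "G", regions=["A", "B"])
        assert np.isnan(m.r.loc["A", "B"])

    def test_matrix_symmetric_with_unit_diagonal(self, study_react):
        m = cn.correlation_matrix(study_react, "CFC")
        np.testing.assert_allclose(m.r.values, m.r.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m.r.values), 1.0)
        off = m.r.values[~np.eye(15, dtype=bool)]
        assert (np.abs(off) <= 1 + 1e-12).all()


class TestBuildNetwork:
    def test_sign_mode_edge_partition(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 3))
        m = matrix_from_values(vals, ["A", "B", "C"])
        pos = cn.build_network(m, "positive")
        neg = cn.build_network(m, "negative")
        comb = cn.build_network(m, "combined")
        for u, v, d in pos.edges(data=True):
            assert d["weight"] > 0 and d["weight"] == m.r.loc[u, v]
        for u, v, d in neg.edges(data=True):
            assert m.r.loc[u, v] < 0 and d["weight"] == abs(m.r.loc[u, v])
        assert pos.number_of_edges() + neg.number_of_edges() == comb.number_of_edges() == 3
        assert not any(u == v for u, v in comb.edges)

    def test_all_positive_matrix_modes(self):
        vals = np.array([[1.0, 2.0, 1.5], [2.0, 4.0, 3.0], [3.0, 5.0, 4.1], [4.0, 8.1, 6.2]])
        m = matrix_from_values(vals, ["A", "B", "C"])
        assert cn.build_network(m, "positive").number_of_edges() == 3
        assert cn.build_network(m, "negative").number_of_edges() == 0

    def test_missing_correlation_gives_no_edge(self):
        m = matrix_from_values(np.random.default_rng(1).normal(size=(5, 3)), ["A", "B", "C"])
        m.r.loc["A", "B"] = m.r.loc["B", "A"] = np.nan
        net = cn.build_network(m, "combined")
        assert not net.has_edge("A", "B")
        assert "A" in net and "B" in net


class TestCentralities:
    def test_triangle_symmetry(self):
        net = _toy_net([("A", "B", 0.4), ("B", "C", 0.4), ("A", "C", 0.4)])
        prof = cn.compute_centralities(net)
        assert prof["Str"].tolist() == pytest.approx([0.4] * 3)
        assert prof["Eig"].tolist() == pytest.approx([1.0] * 3)
        assert prof["CC"].tolist() == pytest.approx([1.0] * 3)

    def test_path_betweenness_counts_pairs(self):
        net = _toy_net([("A", "B", 1.0), ("B", "C", 1.0)])
        prof = cn.compute_centralities(net)
        assert prof.loc["B", "Bet"] == 1.0
        assert prof.loc["A", "Bet"] == 0.0 and prof.loc["C", "Bet"] == 0.0
        # B is one hop from both ends; A averages 1 and 2
        assert prof.loc["B", "Clo"] == pytest.approx(1.0)
        assert prof.loc["A", "Clo"] == pytest.approx(1 / 1.5)

    def test_star_center_dominates_every_measure(self):
        net = _toy_net([("hub", x, 1.0) for x in ("A", "B", "C")])
        prof = cn.compute_centralities(net)
        for c in ("Str", "Eig", "Bet", "Clo"):
            assert prof.loc["hub", c] == prof[c].max()
            assert (prof.drop("hub")[c] < prof.loc["hub", c]).all()

    def test_eigenvector_invariant_under_weight_scaling(self):
        rng = np.random.default_rng(3)
        net = random_weighted_graph(rng)
        prof = cn.compute_centralities(net)
        scaled = net.copy()
        for _, _, d in scaled.edges(data=True):
            d["weight"] *= 7.3
        prof2 = cn.compute_centralities(scaled)
        np.testing.assert_allclose(prof["Eig"], prof2["Eig"], atol=1e-8)

    def test_eigenvector_matches_networkx(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            net = random_weighted_graph(rng)
            if not nx.is_connected(net):
                continue
            prof = cn.compute_centralities(net)
            ref = nx.eigenvector_centrality_numpy(net, weight="weight")
            ref_max = max(ref.values())
            for n in net.nodes:
                assert prof.loc[n, "Eig"] == pytest.approx(ref[n] / ref_max, abs=1e-6)

    def test_clustering_examples(self):
        tri = _toy_net([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])
        assert cn.clustering_coefficient(tri, "A") == 1.0
        star = _toy_net([("hub", x, 1.0) for x in ("A", "B", "C")])
        assert cn.clustering_coefficient(star, "hub") == 0.0
        # 4-clique minus edge (C, D): A neighbors {B, C, D}, among them only
        # B-C and B-D remain -> 2 of 3 possible links
        clique = _toy_net(
            [("A", "B", 1.0), ("A", "C", 1.0), ("A", "D", 1.0), ("B", "C", 1.0), ("B", "D", 1.0)]
        )
        assert cn.clustering_coefficient(clique, "A") == pytest.approx(2 / 3)
        assert cn.clustering_coefficient(clique, "C") == pytest.approx(1.0)

    def test_combined_mode_signed_strength(self):
        net = _toy_net([("A", "B", 0.6), ("A", "C", -0.3)], sign_mode="combined")
        prof = cn.compute_centralities(net)
        s_pos, s_neg = 0.6 / 2, 0.3 / 2  # averaged over the N-1 other regions
        expected = s_pos - (s_neg / (s_pos + s_neg)) * s_neg
        assert prof.loc["A", "Str"] == pytest.approx(expected)
        # path measures use |r|: B and C are reachable through A
        assert prof.loc["A", "Bet"] == 1.0

    def test_disconnected_network_warns_for_eigenvector(self):
        net = _toy_net([("A", "B", 1.0), ("C", "D", 0.5), ("D", "E", 0.5)])
        with pytest.warns(UserWarning, match="disconnected"):
            prof = cn.compute_centralities(net)
        assert prof.loc["A", "Eig"] == 0.0  # not in the largest component
        assert prof.loc["D", "Eig"] == 1.0


class TestHubs:
    def test_candidate_set_size_fifteen_regions(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(15).astype(float)
        prof = pd.DataFrame(
            {c: scores for c in ("Str", "Eig", "Bet", "Clo")},
            index=[f"R{i}" for i in range(15)],
        )
        hubs = cn.identify_hubs(prof)
        assert len(hubs) == math.ceil(0.25 * 15) == 4
        top4 = set(prof["Str"].nlargest(4).index)
        assert hubs == top4

    def test_top_node_in_every_centrality_is_hub(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(
            {c: rng.random(10) for c in ("Str", "Eig", "Bet", "Clo")},
            index=[f"R{i}" for i in range(10)],
        )
        prof.loc["R0"] = 10.0
        assert "R0" in cn.identify_hubs(prof)

    def test_degenerate_profile_makes_everyone_a_hub_with_warning(self):
        prof = pd.DataFrame(
            {c: np.ones(6) for c in ("Str", "Eig", "Bet", "Clo")},
            index=[f"R{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="degenerate"):
            hubs = cn.identify_hubs(prof)
        assert hubs == set(prof.index)


class TestCommunities:
    def test_two_disconnected_triangles(self):
        net = _toy_net(
            [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
             ("X", "Y", 1.0), ("Y", "Z", 1.0), ("X", "Z", 1.0)]
        )
        part = cn.detect_communities(net, seed=0)
        assert part.q == pytest.approx(0.5)
        assert {frozenset(c) for c in part.communities} == {
            frozenset("ABC"), frozenset("XYZ")
        }

    def test_complete_graph_is_one_community(self):
        net = _toy_net([(u, v, 0.8) for u, v in
                        [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]])
        part = cn.detect_communities(net, seed=0)
        assert len(part.communities) == 1

    def test_planted_two_block_network_recovered(self):
        blocks = (["A", "B", "C", "D"], ["W", "X", "Y", "Z"])
        edges = []
        for block in blocks:
            for i, u in enumerate(block):
                for v in block[i + 1:]:
                    edges.append((u, v, 0.8))
        edges.append(("A", "W", 0.05))
        net = _toy_net(edges)
        part = cn.detect_communities(net, seed=0)
        assert {frozenset(c) for c in part.communities} == {frozenset(b) for b in blocks}
        # exhaustive search over all partitions agrees
        best_q, _ = max_modularity(graph_from_nx(net))
        assert part.q == pytest.approx(best_q)

    def test_trivial_partition_scores_zero(self):
        rng = np.random.default_rng(5)
        net = random_weighted_graph(rng)
        membership = {n: 0 for n in net.nodes}
        assert cn.modularity_score(net, membership) == pytest.approx(0.0)

    def test_modularity_matches_direct_formula_and_networkx(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            net = random_weighted_graph(rng)
            membership = {n: int(rng.integers(0, 3)) for n in net.nodes}
            q = cn.modularity_score(net, membership)
            assert q == pytest.approx(modularity(graph_from_nx(net), membership), abs=1e-12)
            comms = [
                {n for n, c in membership.items() if c == k}
                for k in set(membership.values())
            ]
            assert q == pytest.approx(
                nx.community.modularity(net, comms, weight="weight"), abs=1e-12
            )

    def test_partition_must_cover_all_nodes(self):
        net = _toy_net([("A", "B", 1.0), ("B", "C", 1.0)])
        with pytest.raises(cn.ValidationError, match="cover"):
            cn.modularity_score(net, {"A": 0, "B": 0})

    def test_edgeless_network_yields_singletons(self):
        net = _toy_net([])
        net.add_nodes_from(["A", "B", "C"])
        part = cn.detect_communities(net, seed=0)
        assert part.q == 0.0
        assert len(part.communities) == 3

    def test_deterministic_given_seed(self, study_react):
        m = cn.correlation_matrix(study_react, "CFC")
        net = cn.build_network(m, "positive")
        p1 = cn.detect_communities(net, seed=9)
        p2 = cn.detect_communities(net, seed=9)
        assert p1.membership == p2.membership and p1.q == p2.q


class TestTopologyMetrics:
    def test_complete_unit_graph(self):
        net = _toy_net([(u, v, 1.0) for u, v in
                        [("A", "B"), ("A", "C"), ("B", "C")]])
        t = cn.topology_metrics(net)
        assert t["global_efficiency"] == pytest.approx(1.0)
        assert t["avg_clustering"] == pytest.approx(1.0)
        assert t["avg_degree"] == pytest.approx(2.0)

    def test_edgeless_graph_all_zero(self):
        net = _toy_net([])
        net.add_nodes_from(["A", "B"])
        t = cn.topology_metrics(net)
        assert all(v == 0.0 for v in t.values())

    def test_path_graph_efficiency(self):
        net = _toy_net([("A", "B", 1.0), ("B", "C", 1.0)])
        # ordered pairs: 4 at distance 1, 2 at distance 2 -> (4 + 2*0.5)/6
        assert cn.topology_metrics(net)["global_efficiency"] == pytest.approx(5 / 6)


class TestNodeDeletion:
    def _profiled(self, seed=0):
        net, hubs = cn.planted_hub_network(seed=seed)
        prof = cn.compute_centralities(net)
        return net, prof, hubs

    def test_hub_deletion_hurts_more_than_matched_non_hub(self):
        net, prof, _ = self._profiled(seed=1)
        hub_del = cn.node_deletion_efficiency(net, prof, "hubs")
        non_del = cn.node_deletion_efficiency(net, prof, "non_hubs")
        assert len(hub_del["deleted"]) == len(non_del["deleted"])
        assert set(hub_del["deleted"]).isdisjoint(non_del["deleted"])
        assert (
            hub_del["delta"]["global_efficiency"] < non_del["delta"]["global_efficiency"]
        )

    def test_deleting_isolated_node_preserves_remaining_efficiency(self):
        net = _toy_net([("A", "B", 1.0), ("B", "C", 1.0)])
        net.add_node("loner")
        prof = cn.compute_centralities(net)
        prof["hub"] = prof.index == "loner"
        out = cn.node_deletion_efficiency(net, prof, "hubs")
        # 3 remaining nodes: same pair distances as the intact path graph
        assert out["reduced"]["global_efficiency"] == pytest.approx(5 / 6)

    def test_deletion_cannot_empty_network(self):
        net = _toy_net([("A", "B", 1.0)])
        prof = cn.compute_centralities(net)
        prof["hub"] = True
        with pytest.raises(cn.ValidationError, match="empty"):
            cn.node_deletion_efficiency(net, prof, "hubs")


class TestMeanGroupConnectivity:
    def _const_matrix(self, c, regions, anat):
        r = pd.DataFrame(np.full((len(regions), len(regions)), c), index=regions, columns=regions)
        np.fill_diagonal(r.values, 1.0)
        m = cn.GroupCorrelationMatrix("G", list(regions), r, 5)
        return m, anat

    def test_constant_matrix_returns_the_constant(self):
        regions = ["n1", "n2", "n3"]
        anat = {"n1": "amygdala", "n2": "amygdala", "n3": "PH"}
        m, anat = self._const_matrix(0.5, regions, anat)
        for sel in [("amygdala", "PH"), ("amygdala", None)]:
            assert cn.mean_group_connectivity(m, sel[0], sel[1], anat) == pytest.approx(0.5)

    def test_hand_listed_pair_mean(self):
        regions = ["a1", "a2", "h1", "p1"]
        anat = {"a1": "amygdala", "a2": "amygdala", "h1": "hippocampus", "p1": "PH"}
        r = pd.DataFrame(np.eye(4), index=regions, columns=regions)
        vals = {("a1", "h1"): 0.2, ("a1", "p1"): 0.4, ("a2", "h1"): 0.6,
                ("a2", "p1"): 0.8, ("a1", "a2"): -0.9, ("h1", "p1"): -0.7}
        for (u, v), w in vals.items():
            r.loc[u, v] = r.loc[v, u] = w
        m = cn.GroupCorrelationMatrix("G", regions, r, 5)
        assert cn.mean_group_connectivity(m, "amygdala", "hippocampus", anat) == pytest.approx(0.4)
        # vs all others: pairs a-h and a-p only (within-amygdala excluded)
        assert cn.mean_group_connectivity(m, "amygdala", None, anat) == pytest.approx(0.5)

    def test_selector_errors(self):
        regions = ["a1", "p1"]
        anat = {"a1": "amygdala", "p1": "PH"}
        m, _ = self._const_matrix(0.3, regions, anat)
        with pytest.raises(cn.ValidationError, match="non-empty"):
            cn.mean_group_connectivity(m, "mPFC", "PH", anat)
        with pytest.raises(cn.ValidationError, match="disjoint"):
            cn.mean_group_connectivity(m, "amygdala", "amygdala", anat)


class TestExports:
    def test_graphml_and_tsv_round_trip(self, study_react, tmp_path):
        m = cn.correlation_matrix(study_react, "CFC")
        net = cn.build_network(m, "combined")
        prof = cn.compute_centralities(net)
        part = cn.detect_communities(net, seed=0)
        gpath = tmp_path / "net.graphml"
        cn.export_graphml(net, gpath, profile=prof, partition=part)
        loaded = nx.read_graphml(gpath)
        assert loaded.number_of_nodes() == 15
        node = list(loaded.nodes(data=True))[0][1]
        assert {"anatomical_group", "Str", "hub", "community"} <= set(node)
        tpath = tmp_path / "edges.tsv"
        cn.export_edges_tsv(net, tpath)
        edges = pd.read_csv(tpath, sep="\t")
        assert set(edges.columns) == {"source", "target", "weight", "sign"}
        assert len(edges) == net.number_of_edges()
        mpath = tmp_path / "corr.csv"
        cn.export_matrix_csv(m, mpath)
        back = pd.read_csv(mpath, index_col=0)
        np.testing.assert_allclose(back.values, m.r.values, atol=1e-12)
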