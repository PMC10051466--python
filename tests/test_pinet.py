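import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import stressnet as sn
from stressnet.pinet import (build_pinet, classify_profile, cluster_timecourses,
                             identify_mediators, pathway_flow, pathway_profiles,
                             zscore_profile)


def toy_pinet(gene_edges, pathways):
    g = nx.Graph()
    g.add_edges_from(gene_edges)
    return build_pinet(pathways, g)


class TestBuildPinet:
    def test_shared_gene_bridges_pathways(self):
        pin = toy_pinet([], {"A": {"g1", "shared"}, "B": {"shared", "g2"}})
        g = pin.graph()
        assert g.degree("shared") == 2
        paths = list(nx.all_shortest_paths(g, "A", "B"))
        assert paths == [["A", "shared", "B"]]

    def test_disjoint_pathways_disconnected(self):
        pin = toy_pinet([], {"A": {"g1"}, "B": {"g2"}})
        g = pin.graph()
        assert not nx.has_path(g, "A", "B")

    def test_membership_edge_count(self):
        rng = np.random.default_rng(4)
        pathways = {f"P{i}": {f"g{j}" for j in rng.choice(30, rng.integers(2, 9),
                                                          replace=False)}
                    for i in range(5)}
        pin = toy_pinet([], pathways)
        assert len(pin.membership_edges()) == sum(len(m) for m in pathways.values())
        assert len(pin.graph()) == len(pathways) + len(pin.genes)

    def test_empty_pathway_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            toy_pinet([], {"A": {"g1"}, "B": set()})

    def test_single_pathway_rejected(self):
        with pytest.raises(ValueError):
            toy_pinet([], {"A": {"g1"}})


class TestClassifyProfile:
    @pytest.mark.parametrize("series,expected", [
        ([0, 1, 1, 1], "activation"),     # up and stable
        ([0, -1, -1, -1], "deactivation"),  # down and stable
        ([0, 0, 0, 0], "stable"),
        ([0, 1, -1, 1], "other"),
    ])
    def test_rule(self, series, expected):
        assert classify_profile(series, epsilon=0.2) == expected

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            classify_profile([0, 1])

    def test_shift_invariant_and_negation_equivariant(self):
        rng = np.random.default_rng(6)
        swap = {"activation": "deactivation", "deactivation": "activation",
                "stable": "stable", "other": "other"}
        for _ in range(50):
            x = rng.normal(0, 1, 4)
            c = classify_profile(x)
            assert classify_profile(x + 3.7) == c
            assert classify_profile(-x) == swap[c]

    def test_planted_labels_recovered_exactly(self, noiseless_study):
        profs = pathway_profiles(noiseless_study.expression, noiseless_study.pathways)
        got = {p: pr.label for p, pr in profs.items()}
        assert got == noiseless_study.truth.pathway_labels


class TestClusterTimecourses:
    def _subset(self, study, features):
        return sn.ExpressionSeries(study.expression.values.loc[features],
                                   study.expression.samples)

    def test_two_planted_groups_perfectly_separated(self, noiseless_study):
        truth = noiseless_study.truth
        act = [g for p, c in truth.pathway_labels.items() if c == "activation"
               for g in truth.pathway_members[p]]
        stab = [g for p, c in truth.pathway_labels.items() if c == "stable"
                for g in truth.pathway_members[p]]
        expr = self._subset(noiseless_study, act + stab)
        res = cluster_timecourses(expr, None, k=2, seed=3)
        labels = [0] * len(act) + [1] * len(stab)
        assert adjusted_rand_score(labels, res.assignment[act + stab].to_numpy()) == 1.0

    def test_k1_single_cluster(self, noiseless_study):
        expr = self._subset(noiseless_study, noiseless_study.expression.features[:20])
        res = cluster_timecourses(expr, None, k=1, seed=0)
        assert set(res.assignment) == {0}

    def test_same_seed_same_assignment(self, noisy_study):
        expr = self._subset(noisy_study, noisy_study.expression.features[:30])
        r1 = cluster_timecourses(expr, None, k=3, seed=11)
        r2 = cluster_timecourses(expr, None, k=3, seed=11)
        pd.testing.assert_series_equal(r1.assignment, r2.assignment)

    def test_k_too_large_rejected(self, noiseless_study):
        expr = self._subset(noiseless_study, noiseless_study.expression.features[:4])
        with pytest.raises(ValueError):
            cluster_timecourses(expr, None, k=10, seed=0)

    def test_restricted_to_pinet_genes(self, noiseless_study):
        pin = build_pinet(noiseless_study.pathways, noiseless_study.network)
        res = cluster_timecourses(noiseless_study.expression, pin, k=3, seed=1)
        assert set(res.assignment.index) <= pin.genes


class TestPathwayFlow:
    def test_bridged_vs_disconnected(self):
        pin = toy_pinet([("a1", "x"), ("x", "b1")],
                        {"A": {"a1"}, "B": {"b1"}, "C": {"c1"}})
        flow = pathway_flow(pin, tau=1.0)
        assert flow.weight("A", "B") > 0
        assert flow.weight("A", "C") == 0.0

    def test_symmetric_toy_flow(self):
        pin = toy_pinet([("a1", "m"), ("m", "b1")], {"A": {"a1"}, "B": {"b1"}})
        flow = pathway_flow(pin, tau=0.7)
        assert flow.weight("A", "B") == pytest.approx(flow.weight("B", "A"))

    def test_relabeling_invariance(self):
        edges = [("a1", "m"), ("m", "b1"), ("b1", "b2")]
        pin1 = toy_pinet(edges, {"A": {"a1"}, "B": {"b1", "b2"}})
        relab = {"a1": "q", "m": "r", "b1": "s", "b2": "t"}
        pin2 = toy_pinet([(relab[u], relab[v]) for u, v in edges],
                         {"A": {"q"}, "B": {"s", "t"}})
        f1, f2 = pathway_flow(pin1, tau=0.4), pathway_flow(pin2, tau=0.4)
        assert f1.weight("A", "B") == pytest.approx(f2.weight("A", "B"))

    def test_planted_hub_pathway_reaches_downstream(self):
        # MAPK-like hub wired to three downstream pathways, one pathway apart
        edges = []
        pathways = {"hub": {"h1", "h2"}, "down1": {"d1"}, "down2": {"d2"},
                    "down3": {"d3"}, "far": {"f1"}}
        edges += [("h1", "d1"), ("h1", "d2"), ("h2", "d3"), ("d3", "f1")]
        pin = toy_pinet(edges, pathways)
        flow = pathway_flow(pin, tau=0.3)
        weights = {t: flow.weight("hub", t) for t in ("down1", "down2", "down3", "far")}
        top3 = sorted(weights, key=weights.get, reverse=True)[:3]
        assert set(top3) == {"down1", "down2", "down3"}


class TestMediators:
    def test_single_bridge_is_unique_mediator(self):
        pin = toy_pinet([("a1", "cta1"), ("cta1", "b1")], {"A": {"a1"}, "B": {"b1"}})
        med = identify_mediators(pin, "A", "B", tau=0.5)
        assert med["gene"].tolist() == ["cta1"]

    def test_planted_max_heat_bridge_ranks_first(self):
        rng = np.random.default_rng(9)
        edges = [("a1", "bridge"), ("a2", "bridge"), ("bridge", "b1"),
                 ("a1", "slow"), ("slow", "x1"), ("x1", "b1")]
        pin = toy_pinet(edges, {"A": {"a1", "a2"}, "B": {"b1"}})
        med = identify_mediators(pin, "A", "B", tau=0.5)
        # brute force: shortest set-to-set paths and heat ordering
        g = pin.gene_graph
        heat = sn.diffuse(g, {"a1", "a2"}, tau=0.5)
        cands = set()
        for s in ("a1", "a2"):
            for p in nx.all_shortest_paths(g, s, "b1"):
                cands.update(p[1:-1])
        expected = sorted(cands, key=lambda n: (-heat.heat[n], n))
        assert med["gene"].tolist() == expected
        assert med["gene"].iloc[0] == "bridge"

    def test_removing_cut_mediator_kills_flow(self):
        pin = toy_pinet([("a1", "cta1"), ("cta1", "b1")], {"A": {"a1"}, "B": {"b1"}})
        g2 = pin.gene_graph.copy()
        g2.remove_node("cta1")
        pin2 = build_pinet({"A": {"a1"}, "B": {"b1"}}, g2)
        assert pathway_flow(pin2, tau=0.5).weight("A", "B") == 0.0

    def test_no_path_empty(self):
        pin = toy_pinet([], {"A": {"a1"}, "B": {"b1"}})
        assert identify_mediators(pin, "A", "B").empty


class TestZscore:
    def test_constant_profile_maps_to_zeros(self):
        assert np.allclose(zscore_profile([3, 3, 3]), 0.0)
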