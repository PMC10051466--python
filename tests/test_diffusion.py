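import networkx as nx
import numpy as np
import pandas as pd
import pytest

import stressnet as sn
from helpers import oracle_propagation_members, random_graph, series_heat
from stressnet.diffusion import (diffuse, extract_routes, guilt_by_association,
                                 propagation_subnetwork)
from stressnet.network import EDGE_COLUMNS, merge_layers


class TestDiffuse:
    def test_isolated_seed_keeps_all_heat(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        g.add_edge("b", "b")
        h = diffuse(g, {"a"}, tau=50.0)
        assert h.heat["a"] == pytest.approx(1.0)

    def test_complete_graph_long_time_uniform(self):
        g = nx.complete_graph(5)
        h = diffuse(g, {0}, tau=100.0)
        assert np.allclose(h.heat.to_numpy(), 0.2, atol=1e-9)

    def test_matches_series_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_graph(rng, max_nodes=8)
            h = diffuse(g, {"v0"}, tau=0.5)
            oracle = series_heat(g, {"v0"}, 0.5)
            assert max(abs(h.heat[n] - oracle[n]) for n in g.nodes) < 1e-8

    def test_conservation_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = random_graph(rng)
            seeds = {f"v{int(rng.integers(0, g.number_of_nodes()))}"}
            h = diffuse(g, seeds, tau=float(rng.uniform(0.05, 2.0)))
            assert abs(h.total - len(seeds)) < 1e-9
            assert (h.heat >= 0).all()

    def test_semigroup_property(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, max_nodes=10, edge_prob=0.5)
        h1 = diffuse(g, {"v0"}, tau=0.3)
        # restart from h(0.3) by eigen-decomposing manually via two-step diffusion
        nodes = list(g.nodes)
        w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        lap = np.diag(w.sum(axis=1)) - w
        lam, vec = np.linalg.eigh(lap)
        h2 = vec @ (np.exp(-0.7 * lam) * (vec.T @ h1.heat[nodes].to_numpy()))
        direct = diffuse(g, {"v0"}, tau=1.0)
        assert np.allclose(direct.heat[nodes].to_numpy(), h2, atol=1e-8)

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            diffuse(nx.path_graph(3), set())

    def test_probability_weighting_changes_flow(self, noiseless_study):
        net = noiseless_study.network
        seed = noiseless_study.truth.route_nodes[0][0]
        h_unw = diffuse(net, {seed}, tau=0.5)
        h_w = diffuse(net, {seed}, tau=0.5, weight_by_probability=True)
        assert not np.allclose(h_unw.heat.to_numpy(), h_w.heat[h_unw.heat.index].to_numpy())


class TestExtractRoutes:
    def test_planted_route_recovered(self, noiseless_study):
        study = noiseless_study
        net = sn.filter_lncrna_edges(study.network, 0.95)
        g = net.to_undirected()
        for route in study.truth.route_nodes:
            heat = diffuse(g, {route[0]}, tau=0.1)
            sub = extract_routes(heat, g, quantile=0.9)
            assert set(route) <= set(sub.nodes)

    def test_quantile_bounds(self):
        g = nx.path_graph(4)
        heat = diffuse(g, {0}, tau=0.1)
        for q in (0.0, 1.0, -1):
            with pytest.raises(ValueError):
                extract_routes(heat, g, quantile=q)

    def test_disconnected_hot_node_excluded(self):
        g = nx.Graph()
        g.add_edges_from([("s", "a"), ("x", "y")])
        heat = diffuse(g, {"s"}, tau=0.5)
        heat.heat["x"] = 10.0  # force the far component to be hot
        sub = extract_routes(heat, g, quantile=0.5)
        assert "x" not in sub.nodes and "s" in sub.nodes


class TestPropagationSubnetwork:
    def test_worked_example_subnetwork(self, worked_example):
        net, de = worked_example
        sub = propagation_subnetwork(net, de, "X", tau=1.0, quantile=0.85)
        assert sub.members == {"X", "Y", "A", "D"}

    def test_discordant_interactors_leave_seed_and_route_lncrnas(self, worked_example):
        net, de = worked_example
        table = de.table.copy()
        table.loc[table["id"].isin(list("ABCD")), ["status", "padj"]] = ["down", 0.001]
        de_flip = sn.DETable(table)
        sub = propagation_subnetwork(net, de_flip, "X", tau=1.0, quantile=0.85)
        assert sub.surrounding == set()
        assert sub.members == {"X", "Y"}

    def test_ns_seed_rejected(self, worked_example):
        net, de = worked_example
        with pytest.raises(ValueError, match="not differentially expressed"):
            propagation_subnetwork(net, de, "Y")

    def test_seed_without_interactors_warns(self):
        rows = [("X", "A", "lncrna_protein", np.nan, 0.96, False),
                ("Z", "B", "lncrna_protein", np.nan, 0.96, False)]
        net = merge_layers([pd.DataFrame(rows, columns=EDGE_COLUMNS)],
                           node_kinds={"X": "lncRNA", "Z": "lncRNA",
                                       "A": "gene", "B": "gene"})
        table = pd.DataFrame({"id": ["X", "Z", "A", "B"], "log2FC": [1, 1, 0, 0],
                              "padj": [0.001, 0.001, 0.5, 0.5],
                              "status": ["up", "up", "ns", "ns"]})
        de = sn.DETable(table)
        lonely = net.subnetwork({"X", "A", "Z"})  # Z keeps no lncRNA edges
        with pytest.warns(UserWarning, match="no interactors"):
            sub = propagation_subnetwork(lonely, de, "Z")
        assert sub.members == {"Z"}

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_rules(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_genes = int(rng.integers(5, 12))
        genes = [f"p{i}" for i in range(n_genes)]
        lncs = ["L0", "L1"]
        rows = []
        for l in lncs:
            for g in genes:
                if rng.random() < 0.4:
                    rows.append((l, g, "lncrna_protein", np.nan,
                                 float(rng.uniform(0.95, 0.99)), False))
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if rng.random() < 0.3:
                    rows.append((genes[i], genes[j], "ppi", np.nan, np.nan, False))
        if not any(r[0] == "L0" for r in rows):
            rows.append(("L0", genes[0], "lncrna_protein", np.nan, 0.96, False))
        kinds = {l: "lncRNA" for l in lncs} | {g: "gene" for g in genes}
        net = merge_layers([pd.DataFrame(rows, columns=EDGE_COLUMNS)], node_kinds=kinds)
        status = {f: str(rng.choice(["up", "down", "ns"])) for f in genes + lncs}
        status["L0"] = "up"
        de = sn.DETable(pd.DataFrame(
            [(f, 0.0, 0.5 if s == "ns" else 0.001, s) for f, s in status.items()],
            columns=["id", "log2FC", "padj", "status"]))

        sub = propagation_subnetwork(net, de, "L0", tau=0.5, quantile=0.7)
        graph = net.to_undirected()
        lnc_edges = {frozenset((r.source, r.target))
                     for r in net.layer("lncrna_protein").itertuples(index=False)}
        expected = oracle_propagation_members(graph, lnc_edges, status,
                                              net.node_kinds, "L0", sub.route_nodes)
        assert sub.members == expected


class TestGuiltByAssociation:
    def test_majority_term(self):
        out = guilt_by_association(
            {"L": {"p1", "p2", "p3"}},
            {"p1": "degradation", "p2": "degradation", "p3": "metabolic"})
        row = out.iloc[0]
        assert row["top_term"] == "degradation"
        assert row["top_fraction"] == pytest.approx(2 / 3)

    def test_no_targets_unassigned(self):
        out = guilt_by_association({"L": set()}, {})
        assert out.iloc[0]["top_term"] == "unassigned"

    def test_unannotated_counts_unknown(self):
        out = guilt_by_association({"L": {"p1", "p2"}}, {"p1": "metabolic"})
        assert out.iloc[0]["frequencies"] == {"metabolic": 1, "unknown": 1}

    def test_frequencies_match_bruteforce(self):
        rng = np.random.default_rng(8)
        terms = ["life-essential", "membrane-dependent", "metabolic", "degradation"]
        targets = {f"L{i}": {f"p{j}" for j in rng.choice(20, rng.integers(1, 8),
                                                         replace=False)}
                   for i in range(5)}
        ann = {f"p{j}": str(rng.choice(terms)) for j in range(20)}
        out = guilt_by_association(targets, ann).set_index("lncrna")
        for l, ts in targets.items():
            counts = {}
            for p in ts:
                counts[ann[p]] = counts.get(ann[p], 0) + 1
            assert out.loc[l, "frequencies"] == counts
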