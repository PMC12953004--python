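"""Network construction, Zi-Pi roles, robustness and vulnerability."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import biocrustnet as bn
from biocrustnet.network import _cascade_survivors, global_efficiency
from tests.conftest import make_table


def corr_result(rho: np.ndarray, pval: np.ndarray | None = None, taxa=None):
    taxa = taxa or [f"t{i + 1}" for i in range(rho.shape[0])]
    return bn.CorrelationResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        pval=None if pval is None else pd.DataFrame(pval, index=taxa, columns=taxa),
    )


class TestFilterTaxa:
    def test_strict_abundance_and_inclusive_prevalence(self):
        # t1: exactly 0.1% overall -> removed; t2 in 7/9 replicates -> kept
        counts = {f"s{i}": [0, 100, 900] for i in range(1, 10)}
        for i in (1, 2):
            counts[f"s{i}"][1] = 0
        counts["s1"][0] = 9  # t1 total 9 of 9000 = 0.1% exactly
        table = make_table(counts)
        out = bn.filter_taxa(table, min_rel_abund=0.001, min_prevalence=7)
        assert list(out.taxa) == ["t2", "t3"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        counts = {f"s{i}": rng.integers(0, 40, 30) for i in range(9)}
        table = make_table(counts)
        out = bn.filter_taxa(table, min_rel_abund=0.01, min_prevalence=5)
        total = table.counts.values.sum()
        expected = [
            t
            for t in table.taxa
            if table.counts.loc[t].sum() / total > 0.01
            and (table.counts.loc[t] > 0).sum() >= 5
        ]
        assert list(out.taxa) == expected

    def test_empty_result_raises(self):
        table = make_table({"s1": [1, 1], "s2": [1, 1]})
        with pytest.raises(bn.DegenerateInputError):
            bn.filter_taxa(table, min_rel_abund=0.9, min_prevalence=2)


class TestBuildNetwork:
    def test_inclusive_thresholds(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.65
        rho[0, 2] = rho[2, 0] = 0.64
        pval = np.full((3, 3), 0.05)
        net = bn.build_network(corr_result(rho, pval))
        assert net.has_edge("t1", "t2")  # r = 0.65, p = 0.05 kept
        assert not net.has_edge("t1", "t3")  # r = 0.64 excluded
        assert "t3" not in net  # isolated nodes dropped

    def test_negative_edges_pass_by_magnitude(self):
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = -0.8
        net = bn.build_network(corr_result(rho))
        assert net["t1"]["t2"]["sign"] == "-"

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (15, 15))
        rho = (x + x.T) / 2
        np.fill_diagonal(rho, 1.0)
        p = (rng.uniform(0, 0.1, (15, 15)) + rng.uniform(0, 0.1, (15, 15)).T) / 2
        net = bn.build_network(corr_result(rho, p), r_min=0.4, p_max=0.05)
        expected = sum(
            1
            for i, j in itertools.combinations(range(15), 2)
            if abs(rho[i, j]) >= 0.4 and p[i, j] <= 0.05
        )
        assert net.number_of_edges() == expected

    def test_no_edges_raises(self):
        with pytest.raises(bn.DegenerateInputError):
            bn.build_network(corr_result(np.eye(4)))


class TestModulesAndTopology:
    def test_two_cliques_found_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(6))
        part = bn.detect_modules(g)
        assert {frozenset(k for k, m in part.items() if m == mid) for mid in set(part.values())} == {
            frozenset(range(5)),
            frozenset(range(5, 11)),
        }

    def test_partition_recovers_planted_modules(self, keystone_fixture):
        g, truth = keystone_fixture
        part = bn.detect_modules(g)
        from sklearn.metrics import adjusted_rand_score

        nodes = sorted(g.nodes)
        ari = adjusted_rand_score(
            [truth["module_of"][v] for v in nodes], [part[v] for v in nodes]
        )
        assert ari >= 0.9

    def test_partition_deterministic(self, keystone_fixture):
        g, _ = keystone_fixture
        assert bn.detect_modules(g) == bn.detect_modules(g)

    def test_triangle_and_star_summaries(self):
        tri = bn.topology_summary(nx.complete_graph(3))
        assert tri["density"] == pytest.approx(1.0)
        assert tri["clustering"] == pytest.approx(1.0)
        star = bn.topology_summary(nx.star_graph(5))  # 6 nodes, 5 edges
        assert star["mean_degree"] == pytest.approx(2 * 5 / 6)

    def test_summary_matches_independent_recomputation(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        s = bn.topology_summary(g)
        n, m = g.number_of_nodes(), g.number_of_edges()
        assert s["nodes"] == n and s["edges"] == m
        assert s["density"] == pytest.approx(2 * m / (n * (n - 1)))
        # clustering oracle: triangles over connected triples per node
        cc = []
        for v in g:
            nbrs = list(g[v])
            k = len(nbrs)
            if k < 2:
                cc.append(0.0)
                continue
            links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
            cc.append(2 * links / (k * (k - 1)))
        assert s["clustering"] == pytest.approx(np.mean(cc))


class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self):
        g = nx.complete_graph(5)
        zp = bn.zipi(g, {v: 0 for v in g})
        assert (zp["pi"] == 0).all()

    def test_four_way_split_pi(self):
        g = nx.star_graph(4)  # hub 0 with 4 leaves
        partition = {0: 0, 1: 1, 2: 2, 3: 3, 4: 0}
        zp = bn.zipi(g, partition)
        # hub degree 4 split over 4 modules, one leaf in its own module
        assert zp.loc[0, "pi"] == pytest.approx(0.75)

    def test_matches_direct_formula_on_fixture(self, keystone_fixture):
        g, truth = keystone_fixture
        partition = truth["module_of"]
        zp = bn.zipi(g, partition)
        # independent straight transcription over the edge list
        for node in list(g.nodes)[:25]:
            m = partition[node]
            k_in = sum(1 for nb in g[node] if partition[nb] == m)
            member_kins = [
                sum(1 for nb in g[v] if partition[nb] == m)
                for v in g
                if partition[v] == m
            ]
            sd = np.std(member_kins)
            zi = 0.0 if sd == 0 else (k_in - np.mean(member_kins)) / sd
            k = g.degree(node)
            pi = 1.0 - sum(
                (sum(1 for nb in g[node] if partition[nb] == s) / k) ** 2
                for s in set(partition.values())
            )
            assert zp.loc[node, "zi"] == pytest.approx(zi, abs=1e-12)
            assert zp.loc[node, "pi"] == pytest.approx(pi, abs=1e-12)

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(1, 2)
        zp = bn.zipi(g, {0: 0, 1: 0, 2: 0})
        assert zp.loc[0, "zi"] == 0.0 and zp.loc[0, "pi"] == 0.0


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (3.0, 0.7, "network_hub"),
            (3.0, 0.5, "module_hub"),
            (2.0, 0.7, "connector"),
            (0.0, 0.0, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundary values are not keystones
        ],
    )
    def test_role_thresholds(self, zi, pi, role):
        df = pd.DataFrame({"module": [0], "zi": [zi], "pi": [pi]}, index=["x"])
        assert bn.classify_roles(df).loc["x", "role"] == role


class TestRobustness:
    def test_complete_graph_no_cascade(self):
        g = nx.complete_graph(10)
        vals = bn.robustness_random(g, fraction=0.5, n_perm=20, rng_seed=0)
        assert np.allclose(vals, 0.5)

    def test_star_hub_removal_collapses(self):
        g = nx.star_graph(9)  # hub 0 + 9 leaves
        curve = bn.robustness_targeted(g, [0])
        assert curve == [0.0]

    def test_targeted_curve_non_increasing(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            g = nx.gnp_random_graph(25, 0.12, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            order = list(rng.permutation(list(g.nodes)))
            curve = bn.robustness_targeted(g, order)
            assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:]))
            assert all(0 <= v <= 1 for v in curve)

    def test_cascade_idempotent(self):
        g = nx.gnp_random_graph(30, 0.08, seed=2)
        removed = list(g.nodes)[:10]
        once = _cascade_survivors(g, removed)
        again = _cascade_survivors(g.subgraph(once).copy(), [])
        assert once == again

    def test_restricted_pool(self):
        g = nx.complete_graph(10)
        vals = bn.robustness_random(g, fraction=1.0, n_perm=5, rng_seed=0, restrict_to=[0, 1])
        assert np.allclose(vals, 0.8)

    def test_unknown_nodes_rejected(self):
        with pytest.raises(bn.BiocrustError):
            bn.robustness_targeted(nx.complete_graph(3), ["zz"])


class TestVulnerability:
    def test_path_p3_total(self):
        assert bn.vulnerability(nx.path_graph(3)) == pytest.approx(1.0)

    def test_complete_k4_zero(self):
        assert bn.vulnerability(nx.complete_graph(4)) == pytest.approx(0.0)

    def test_matches_bfs_oracle(self):
        def oracle(g):
            def eff(h):
                nodes = list(h.nodes)
                tot = 0.0
                for a, b in itertools.combinations(nodes, 2):
                    # manual BFS
                    seen = {a: 0}
                    frontier = [a]
                    while frontier and b not in seen:
                        nxt = []
                        for v in frontier:
                            for nb in h[v]:
                                if nb not in seen:
                                    seen[nb] = seen[v] + 1
                                    nxt.append(nb)
                        frontier = nxt
                    if b in seen:
                        tot += 1.0 / seen[b]
                n = len(nodes)
                return 2.0 * tot / (n * (n - 1)) if n > 1 else 0.0

            e = eff(g)
            return max((e - eff(g.subgraph(set(g) - {v}))) / e for v in g)

        for seed in range(8):
            g = nx.gnp_random_graph(12, 0.25, seed=seed)
            if g.number_of_edges() == 0:
                continue
            assert bn.vulnerability(g) == pytest.approx(oracle(g), abs=1e-12)

    def test_zero_efficiency_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        with pytest.raises(bn.BiocrustError):
            bn.vulnerability(g)


class TestGroupComparison:
    def test_group_with_no_presence_is_null_comparison(self):
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        g.remove_nodes_from(list(nx.isolates(g)))
        nx.set_node_attributes(g, False, "is_cyanobacterium")
        res = bn.compare_with_without_group(g, "is_cyanobacterium", n_perm=30, rng_seed=0)
        assert res.n_nodes_with == res.n_nodes_without
        assert res.p_value > 0.99

    def test_connector_group_lowers_robustness(self):
        g, truth = bn.plant_keystone_network(
            100, 4, rng_seed=13, p_within=0.05, p_between=0.0,
            n_connectors=4, connector_coverage=0.25,
        )
        for c in truth["connectors"]:
            g.nodes[c]["is_cyanobacterium"] = True
        res = bn.compare_with_without_group(g, "is_cyanobacterium", rng_seed=13)
        assert (
            res.stability_with.robustness_samples["random"].mean()
            > res.stability_without.robustness_samples["random"].mean()
        )
        assert res.p_value < 0.05

    def test_without_network_matches_brute_force_deletion(self, keystone_fixture):
        g, truth = keystone_fixture
        group = set(truth["connectors"])
        from biocrustnet.network import remove_group

        cyr = remove_group(g, group)
        assert set(cyr.nodes) == set(g.nodes) - group
        expected_edges = {e for e in g.edges if not set(e) & group}
        assert {tuple(sorted(e)) for e in cyr.edges} == {
            tuple(sorted(e)) for e in expected_edges
        }


class TestFocalSubnetwork:
    def make_net(self):
        g = nx.Graph()
        g.add_edge("c1", "b1", sign="+")
        g.add_edge("c1", "f1", sign="-")
        g.add_edge("b1", "b2", sign="+")
        g.add_edge("b2", "b3", sign="+")
        for v in g:
            g.nodes[v]["kingdom"] = "Fungi" if v.startswith("f") else "Bacteria"
            g.nodes[v]["is_cyanobacterium"] = v.startswith("c")
        return g

    def test_group_node_plus_neighbours(self):
        sub, summary = bn.extract_focal_subnetwork(self.make_net())
        assert set(sub.nodes) == {"c1", "b1", "f1"}
        assert summary["n_group_nodes"] == 1
        assert summary["group_share_of_prokaryotes"] == pytest.approx(1 / 4)
        assert summary["connected_fraction"] == pytest.approx(2 / 4)
        assert summary["positive_fraction_bacteria"] == 1.0
        assert summary["positive_fraction_fungi"] == 0.0

    def test_group_all_nodes_returns_whole_network(self):
        g = self.make_net()
        sub, _ = bn.extract_focal_subnetwork(g, group=list(g.nodes))
        assert set(sub.nodes) == set(g.nodes)
        assert set(sub.edges) == set(g.edges)
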