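"""Co-occurrence networks: thresholding, topology vs brute force, ER nulls."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chronet import (
    CorrelationNetwork,
    SimulationConfig,
    TaxonomyTable,
    build_network,
    er_null_ensemble,
    extract_subnetwork,
    family_correlations,
    modularity_score,
    phylum_link_summary,
    simulate_dataset,
    small_world_assessment,
    topology,
    topology_vs_age,
    topology_vs_soil,
)
from chronet.types import ValidationError


# ---------------------------------------------------------------------------
# brute-force oracles (pure python, BFS/enumeration)

def bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_topology(g: nx.Graph):
    nodes = list(g.nodes)
    n = len(nodes)
    adj = {u: set(g.neighbors(u)) for u in nodes}
    # all-pairs shortest paths over reachable pairs
    lengths = []
    for i, u in enumerate(nodes):
        du = bfs_distances(adj, u)
        for v in nodes[i + 1:]:
            if v in du:
                lengths.append(du[v])
    apl = float(np.mean(lengths)) if lengths else 0.0
    diameter = float(max(lengths)) if lengths else 0.0
    # direct triangle counting for local clustering
    locals_ = []
    for u in nodes:
        k = len(adj[u])
        if k < 2:
            locals_.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(adj[u], 2) if b in adj[a]
        )
        locals_.append(links / (k * (k - 1) / 2))
    clustering = float(np.mean(locals_)) if locals_ else 0.0
    # exhaustive betweenness: enumerate all shortest paths per pair
    bw = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        ds = bfs_distances(adj, s)
        if t not in ds:
            continue
        shortest = []
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                shortest.append(path)
                continue
            for v in adj[u]:
                # extend only along shortest-path DAG edges
                if v in ds and ds[v] == len(path):
                    stack.append((v, path + [v]))
        shortest = [p for p in shortest if len(p) - 1 == ds[t]]
        if not shortest:
            continue
        for p in shortest:
            for v in p[1:-1]:
                bw[v] += 1.0 / len(shortest)
    if n > 2:
        scale = (n - 1) * (n - 2) / 2.0
        bnorm = {u: bw[u] / scale for u in nodes}
        bmax = max(bnorm.values())
        centralization = sum(bmax - b for b in bnorm.values()) / (n - 1)
    else:
        centralization = 0.0
    return {
        "average_path_length": apl,
        "diameter": diameter,
        "graph_density": 2.0 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0,
        "average_degree": 2.0 * g.number_of_edges() / n,
        "clustering_coefficient": clustering,
        "centralization_betweenness": centralization,
    }


def brute_modularity(g: nx.Graph, communities):
    m = g.number_of_edges()
    q = 0.0
    for c in communities:
        cs = set(c)
        e_c = sum(1 for u, v in g.edges if u in cs and v in cs)
        d_c = sum(d for _, d in g.degree(cs))
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------

def _matrices(values, names=("f1", "f2", "f3")):
    return pd.DataFrame(values, index=list(names), columns=list(names))


class TestFamilyCorrelations:
    def test_identical_profiles_rho_one(self):
        df = pd.DataFrame(
            {"f1": [1, 5, 2, 9], "f2": [2, 10, 4, 18], "f3": [4, 1, 7, 2]},
            index=list("abcd"),
        )
        rho, p = family_correlations(df)
        assert rho.loc["f1", "f2"] == pytest.approx(1.0)

    def test_constant_family_excluded(self):
        df = pd.DataFrame(
            {"f1": [1, 5, 2, 9], "flat": [3, 3, 3, 3], "f3": [4, 1, 7, 2]},
            index=list("abcd"),
        )
        rho, _ = family_correlations(df)
        assert "flat" not in rho.columns

    def test_symmetry_exact(self, rng):
        df = pd.DataFrame(rng.integers(0, 50, size=(8, 10)),
                          columns=[f"f{i}" for i in range(10)])
        rho, p = family_correlations(df)
        assert (rho.to_numpy() == rho.to_numpy().T).all()
        assert (p.to_numpy() == p.to_numpy().T).all()

    def test_matches_scipy_spearman(self, rng):
        from scipy.stats import spearmanr
        df = pd.DataFrame(rng.normal(size=(12, 6)), columns=list("abcdef"))
        rho, p = family_correlations(df)
        ref_rho, ref_p = spearmanr(df.to_numpy())
        np.testing.assert_allclose(rho.to_numpy(), ref_rho, atol=1e-12)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(p.to_numpy()[off], ref_p[off], atol=1e-9)

    def test_too_few_samples(self):
        df = pd.DataFrame({"f1": [1, 2, 3], "f2": [3, 2, 1]})
        with pytest.raises(ValidationError, match="4 samples"):
            family_correlations(df)


class TestBuildNetwork:
    def _net(self, rho12, p12, **kwargs):
        rho = _matrices([[1, rho12, 0.1], [rho12, 1, 0.0], [0.1, 0.0, 1]])
        p = _matrices([[0, p12, 0.9], [p12, 0, 0.9], [0.9, 0.9, 0]])
        return build_network(rho, p, use_fdr=False, **kwargs)

    def test_edge_kept_when_both_thresholds_met(self):
        net = self._net(0.85, 0.005)
        assert net.edge_set() == {("f1", "f2")}
        assert net.graph.edges["f1", "f2"]["sign"] == "positive"

    def test_edge_dropped_when_p_fails(self):
        assert self._net(0.85, 0.02).n_edges == 0

    def test_negative_edge_sign(self):
        net = self._net(-0.9, 0.001)
        assert net.graph.edges["f1", "f2"]["sign"] == "negative"

    def test_fdr_adjustment_is_applied(self):
        # raw p 0.009 passes 0.01; BH over 3 tests inflates it past 0.01
        rho = _matrices([[1, 0.9, 0.1], [0.9, 1, 0.0], [0.1, 0.0, 1]])
        p = _matrices([[0, 0.009, 0.9], [0.009, 0, 0.9], [0.9, 0.9, 0]])
        assert build_network(rho, p, use_fdr=False).n_edges == 1
        assert build_network(rho, p, use_fdr=True).n_edges == 0

    def test_threshold_monotonicity(self, rng):
        m = 12
        names = [f"f{i}" for i in range(m)]
        r = rng.uniform(-1, 1, size=(m, m))
        r = np.clip((r + r.T) / 2, -0.999, 0.999)
        np.fill_diagonal(r, 1.0)
        p = rng.uniform(size=(m, m)) * 0.05
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0.0)
        rho_df, p_df = _matrices(r, names), _matrices(p, names)
        base = build_network(rho_df, p_df, r_threshold=0.5, p_threshold=0.02).edge_set()
        stricter_r = build_network(rho_df, p_df, r_threshold=0.7, p_threshold=0.02).edge_set()
        stricter_p = build_network(rho_df, p_df, r_threshold=0.5, p_threshold=0.005).edge_set()
        assert stricter_r <= base and stricter_p <= base

    def test_mismatched_indices_rejected(self):
        rho = _matrices(np.eye(3))
        p = _matrices(np.zeros((3, 3)), names=("g1", "g2", "g3"))
        with pytest.raises(ValidationError, match="indices"):
            build_network(rho, p)

    def test_node_attributes_attached(self):
        tax = TaxonomyTable(pd.DataFrame(
            {"phylum": ["Proteobacteria", "Acidobacteria", "Firmicutes"],
             "family": ["f1", "f2", "f3"]},
            index=["f1", "f2", "f3"],
        ))
        ab = pd.DataFrame({"f1": [10, 20], "f2": [30, 40], "f3": [60, 40]})
        net = self._net(0.85, 0.005, taxonomy=tax, abundances=ab)
        assert net.graph.nodes["f1"]["phylum"] == "Proteobacteria"
        assert 0 < net.graph.nodes["f1"]["abundance"] < 1


class TestSubnetwork:
    def _triangle(self):
        g = nx.Graph()
        for pair in [("f1", "f2"), ("f2", "f3"), ("f1", "f3")]:
            g.add_edge(*pair, rho=0.9, p_raw=1e-4, p_adj=1e-3, sign="positive")
        return CorrelationNetwork(g, group="Y90")

    def test_all_families_present_is_identity(self):
        net = self._triangle()
        sub = extract_subnetwork(net, pd.Series({"f1": 5, "f2": 1, "f3": 2}))
        assert sub.edge_set() == net.edge_set()

    def test_no_families_present_is_empty(self):
        sub = extract_subnetwork(self._triangle(), pd.Series({"f1": 0, "f2": 0}))
        assert sub.n_nodes == 0 and sub.n_edges == 0

    def test_induced_subgraph_drops_incident_edges(self):
        sub = extract_subnetwork(
            self._triangle(), pd.Series({"f1": 5, "f2": 1, "f3": 0})
        )
        assert sub.edge_set() == {("f1", "f2")}


class TestTopology:
    def test_path_graph_p4(self):
        t = topology(nx.path_graph(4))
        assert t.average_path_length == pytest.approx(10 / 6)
        assert t.diameter == 3
        assert t.graph_density == pytest.approx(0.5)

    def test_complete_graph_k4(self):
        t = topology(nx.complete_graph(4))
        assert t.clustering_coefficient == pytest.approx(1.0)
        assert t.graph_density == pytest.approx(1.0)
        assert t.average_path_length == pytest.approx(1.0)

    def test_star_centralization_is_one(self):
        t = topology(nx.star_graph(4))  # hub + 4 leaves
        assert t.centralization_betweenness == pytest.approx(1.0)

    def test_disconnected_average_over_reachable_pairs(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        t = topology(g)
        assert t.average_path_length == pytest.approx(1.0)
        assert t.diameter == 1

    def test_single_node_degenerate(self):
        g = nx.Graph()
        g.add_node("a")
        t = topology(g)
        assert t.degenerate and t.average_path_length == 0.0

    @pytest.mark.parametrize("batch", range(4))
    def test_brute_force_equivalence_on_random_graphs(self, batch):
        rng = np.random.default_rng(batch)
        for rep in range(50):
            n = int(rng.integers(2, 8))
            max_m = n * (n - 1) // 2
            m = int(rng.integers(0, max_m + 1))
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            ours = topology(g).as_dict()
            ref = brute_topology(g)
            for key, val in ref.items():
                assert ours[key] == pytest.approx(val, abs=1e-9), (key, n, m)


class TestModularity:
    def _two_cliques_with_bridge(self):
        g = nx.Graph()
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        for grp in (left, right):
            g.add_edges_from(itertools.combinations(grp, 2))
        g.add_edge("l0", "r0")
        return g, [set(left), set(right)]

    def test_two_clique_bridge_worked_example(self):
        g, part = self._two_cliques_with_bridge()
        q = modularity_score(g, part)
        expected = 2 * (6 / 13 - (13 / 26) ** 2)
        assert q == pytest.approx(expected, abs=1e-12)
        assert q == pytest.approx(0.4231, abs=5e-5)

    def test_single_community_q_zero(self):
        g = nx.complete_graph(5)
        assert modularity_score(g, [set(g.nodes)]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_formula_on_random_partitions(self, rng):
        for rep in range(30):
            g = nx.gnm_random_graph(8, 12, seed=rep)
            labels = rng.integers(0, 3, size=8)
            part = [set(np.where(labels == k)[0]) for k in range(3)]
            part = [c for c in part if c]
            assert modularity_score(g, part) == pytest.approx(
                brute_modularity(g, part), abs=1e-12
            )

    def test_greedy_partition_dominates_singletons(self):
        for seed in range(100):
            g = nx.gnm_random_graph(12, 20, seed=seed)
            q_greedy = topology(g).modularity
            q_single = modularity_score(g, [{n} for n in g.nodes])
            assert q_greedy >= q_single - 1e-12

    def test_empty_graph_errors(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValidationError, match="modularity undefined"):
            modularity_score(g, [{"a"}, {"b"}])

    def test_bad_partition_errors(self):
        g = nx.path_graph(3)
        with pytest.raises(ValidationError, match="cover"):
            modularity_score(g, [{0, 1}])
        with pytest.raises(ValidationError, match="overlap"):
            modularity_score(g, [{0, 1}, {1, 2}])


class TestErNullEnsemble:
    def test_density_exact_for_every_graph(self):
        ens = er_null_ensemble(20, 38, n_graphs=200, seed=0)
        expected = 38 / (20 * 19 / 2)
        np.testing.assert_allclose(ens.metrics["graph_density"], expected, atol=1e-12)

    def test_determinism(self):
        a = er_null_ensemble(15, 30, n_graphs=50, seed=3)
        b = er_null_ensemble(15, 30, n_graphs=50, seed=3)
        for k in a.metrics:
            np.testing.assert_array_equal(a.metrics[k], b.metrics[k])

    def test_impossible_edge_count(self):
        with pytest.raises(ValidationError, match="impossible"):
            er_null_ensemble(5, 11)

    def test_uniformity_over_small_graph_space(self):
        """G(3,1) has 3 equally likely graphs; edge choice should be uniform."""
        rng_counts = np.zeros(3)
        from chronet.network import _sample_gnm_edges
        rng = np.random.default_rng(0)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for _ in range(3000):
            e = _sample_gnm_edges(rng, 3, 1)[0]
            rng_counts[pairs[tuple(e)]] += 1
        assert rng_counts.min() > 900  # ~1000 each


class TestSmallWorld:
    def test_null_draw_rarely_flagged(self):
        ens = er_null_ensemble(30, 60, n_graphs=300, seed=1)
        flags = {m: 0 for m in ("clustering_coefficient", "modularity")}
        reps = 40
        rng = np.random.default_rng(2)
        for i in range(reps):
            topo_like = topology(_gnm_nx(30, 60, int(rng.integers(2**31))))
            sw = small_world_assessment(topo_like, ens)
            for m in flags:
                flags[m] += sw.higher_than_null[m]
        for m, count in flags.items():
            assert count / reps <= 0.2, m

    def test_lattice_clustering_flagged(self):
        lattice = nx.watts_strogatz_graph(30, 6, p=0.0, seed=0)  # ring lattice
        t = topology(lattice)
        ens = er_null_ensemble(t.n_nodes, t.n_edges, n_graphs=300, seed=5)
        sw = small_world_assessment(t, ens)
        assert sw.higher_than_null["clustering_coefficient"]
        assert sw.ratios["clustering_coefficient"] > 2

    def test_size_mismatch_rejected(self):
        t = topology(nx.complete_graph(5))
        ens = er_null_ensemble(6, 10, n_graphs=10, seed=0)
        with pytest.raises(ValidationError, match="does not match"):
            small_world_assessment(t, ens)


def _gnm_nx(n, m, seed):
    return nx.gnm_random_graph(n, m, seed=seed)


class TestPhylumLinks:
    def _net(self, edges, phyla):
        g = nx.Graph()
        for node, ph in phyla.items():
            g.add_node(node, phylum=ph)
        for u, v in edges:
            g.add_edge(u, v, rho=0.9, sign="positive")
        return CorrelationNetwork(g)

    def test_single_phylum_all_on_diagonal(self):
        net = self._net([("a", "b"), ("b", "c")],
                        {x: "Proteobacteria" for x in "abc"})
        mat = phylum_link_summary(net)
        assert mat.loc["Proteobacteria", "Proteobacteria"] == 2

    def test_conservation_of_edge_count(self, rng):
        phyla = {f"n{i}": f"P{i % 4}" for i in range(10)}
        g = nx.gnm_random_graph(10, 18, seed=1)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(10)})
        for n, ph in phyla.items():
            g.nodes[n]["phylum"] = ph
        net = CorrelationNetwork(g)
        mat = phylum_link_summary(net)
        total = np.triu(mat.to_numpy()).sum()
        assert total == net.n_edges

    def test_three_phylum_hand_count(self):
        net = self._net(
            [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")],
            {"a": "P1", "b": "P1", "c": "P2", "d": "P3"},
        )
        mat = phylum_link_summary(net)
        assert mat.loc["P1", "P1"] == 1   # a-b
        assert mat.loc["P1", "P2"] == 2   # a-c, b-c
        assert mat.loc["P2", "P3"] == 1   # c-d
        assert mat.loc["P2", "P2"] == 0


class TestTrendCorrelations:
    def test_exponential_parameter_gives_r_one(self):
        ages = pd.Series([3.0, 10, 43, 90], index=list("abcd"))
        topo = pd.DataFrame({"param": np.exp(ages * 0.05)}, index=list("abcd"))
        res = topology_vs_age(topo, ages)
        assert res.loc["param", "r"] == pytest.approx(1.0)

    def test_constant_parameter_skipped(self):
        ages = pd.Series([3.0, 10, 43, 90], index=list("abcd"))
        topo = pd.DataFrame(
            {"flat": [2.0, 2, 2, 2], "ok": [1.0, 2, 3, 4]}, index=list("abcd")
        )
        res = topology_vs_age(topo, ages)
        assert "flat" not in res.index and "ok" in res.index

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        ages = pd.Series(np.tile([3.0, 10, 43, 90], 3))
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            topo = pd.DataFrame({"param": np.exp(rng.normal(size=12))})
            res = topology_vs_age(topo, ages)
            rejections += res.loc["param", "p"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_soil_duplicated_column_rho_one_and_stars(self):
        rng = np.random.default_rng(1)
        topo = pd.DataFrame({"apl": rng.normal(size=10)})
        soil = pd.DataFrame({"fake": topo["apl"], "TOC": rng.normal(size=10)})
        rho, p, stars = topology_vs_soil(topo, soil)
        assert rho.loc["apl", "fake"] == pytest.approx(1.0)
        assert (rho.abs().to_numpy() <= 1.0 + 1e-12).all()

    def test_star_annotation_rule(self):
        from chronet.network import _stars
        assert _stars(0.004) == "**"
        assert _stars(0.0004) == "***"
        assert _stars(0.04) == "*"
        assert _stars(0.06) == ""
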