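"""Network medicine: thresholded graphs, BFS distances, d_s, d_AB, nulls."""

import networkx as nx
import numpy as np
import pytest

from chronet.atlas import ExpressionAtlas
from chronet.genesets import EdgeList, GeneSet
from chronet.medicine import (
    DegreeBinSampler,
    UnweightedGraph,
    build_unweighted_network,
    day_night_module_difference,
    disease_module_distance,
    disease_module_significance,
    graph_from_edges,
    proximity_dAB,
    proximity_significance,
    shortest_distances,
)
from chronet.simulate import SimulationConfig, simulate_atlas, simulate_interactome


def path_graph(n):
    g = nx.path_graph(n)
    return UnweightedGraph(nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)}))


def random_graph(n=100, p=0.05, seed=0):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return UnweightedGraph(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))


class TestBuildUnweightedNetwork:
    def test_identical_genes_linked(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, (6, 4))
        values = np.stack([base, 2 * base, rng.uniform(1, 10, (6, 4))])
        atlas = ExpressionAtlas(["A", "B", "C"], [f"o{i}" for i in range(6)],
                                np.arange(0, 24, 6.0), values)
        graph = build_unweighted_network(atlas, zt=0.0, restrict_to_lcc=False)
        assert graph.graph.has_edge("A", "B")

    def test_threshold_boundary_collinear_only(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, (6, 4))
        noisy = base + rng.normal(0, 0.5, (6, 4))
        values = np.stack([base, 3 * base + 1, noisy])
        atlas = ExpressionAtlas(["A", "B", "C"], [f"o{i}" for i in range(6)],
                                np.arange(0, 24, 6.0), values)
        graph = build_unweighted_network(atlas, zt=0.0,
                                         r_threshold=1.0 - 1e-9,
                                         restrict_to_lcc=False)
        assert set(map(tuple, map(sorted, graph.graph.edges))) == {("A", "B")}

    def test_planted_correlated_block_connected(self):
        cfg = SimulationConfig(n_genes=60, n_organs=25, seed=71,
                               shared_factor_strength=2.0)
        atlas, _ = simulate_atlas(cfg)
        graph = build_unweighted_network(atlas, zt=6.0, r_threshold=0.5)
        assert nx.is_connected(graph.graph)

    def test_no_edges_advises_threshold(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 10, (4, 8, 4))
        atlas = ExpressionAtlas([f"g{i}" for i in range(4)],
                                [f"o{i}" for i in range(8)],
                                np.arange(0, 24, 6.0), values)
        with pytest.raises(ValueError, match="threshold"):
            build_unweighted_network(atlas, zt=0.0, r_threshold=0.999999)


class TestShortestDistances:
    def test_path_graph_cases(self):
        g = path_graph(5)
        table = shortest_distances(g, ["n0"], ["n2", "n0"])
        assert table.loc["n0", "n2"] == 2
        assert table.loc["n0", "n0"] == 0

    def test_unknown_node_named(self):
        with pytest.raises(KeyError, match="zzz"):
            shortest_distances(path_graph(3), ["zzz"], ["n0"])

    def test_matrix_power_reachability_oracle(self):
        """BFS hop counts agree with first-reach exponents of the adjacency
        matrix."""
        g = random_graph(60, 0.06, seed=3)
        n = g.n
        adj = np.zeros((n, n))
        for a, b in g.graph.edges:
            i, j = g.index_of([a])[0], g.index_of([b])[0]
            adj[i, j] = adj[j, i] = 1
        reach = np.eye(n, dtype=bool)
        dist_oracle = np.full((n, n), np.inf)
        np.fill_diagonal(dist_oracle, 0)
        power = np.eye(n)
        for step in range(1, n):
            power = power @ adj
            newly = (power > 0) & ~reach
            dist_oracle[newly] = step
            reach |= newly
            if reach.all():
                break
        np.testing.assert_allclose(g.distance_matrix(), dist_oracle)


class TestDiseaseModuleDistance:
    def test_adjacent_genes_distance_one(self):
        res = disease_module_distance(path_graph(5),
                                      GeneSet("d", frozenset({"n1", "n2"})))
        assert res["d_s"] == 1.0

    def test_path_endpoints(self):
        res = disease_module_distance(path_graph(5),
                                      GeneSet("d", frozenset({"n0", "n4"})))
        assert res["d_s"] == 4.0

    def test_brute_force_oracle(self):
        g = random_graph(80, 0.06, seed=4)
        genes = g.nodes[::7]
        res = disease_module_distance(g, GeneSet("d", frozenset(genes)))
        spl = dict(nx.all_pairs_shortest_path_length(g.graph))
        brute = np.mean([
            min(spl[a][b] for b in genes if b != a) for a in genes
        ])
        assert res["d_s"] == pytest.approx(brute)

    def test_single_mapped_gene_flagged(self):
        res = disease_module_distance(path_graph(4),
                                      GeneSet("d", frozenset({"n0", "zz"})))
        assert not res["defined"]


class TestProximity:
    def test_identical_sets_zero(self):
        g = random_graph(50, 0.1, seed=5)
        s = GeneSet("s", frozenset(g.nodes[:8]))
        assert proximity_dAB(g, s, s)["d_ab"] == 0.0

    def test_path_hand_computation(self):
        g = path_graph(3)
        res = proximity_dAB(g, GeneSet("a", frozenset({"n0"})),
                            GeneSet("b", frozenset({"n2"})))
        assert res["d_ab"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_oracle_and_symmetry(self, seed):
        g = random_graph(70, 0.07, seed=seed)
        rng = np.random.default_rng(seed)
        a = frozenset(rng.choice(g.nodes, 6, replace=False))
        b = frozenset(rng.choice(g.nodes, 9, replace=False))
        sa, sb = GeneSet("a", a), GeneSet("b", b)
        res = proximity_dAB(g, sa, sb)
        spl = dict(nx.all_pairs_shortest_path_length(g.graph))
        brute = (
            sum(min(spl[x][y] for y in b) for x in a)
            + sum(min(spl[x][y] for y in a) for x in b)
        ) / (len(a) + len(b))
        assert res["d_ab"] == pytest.approx(brute)
        assert proximity_dAB(g, sb, sa)["d_ab"] == pytest.approx(res["d_ab"])

    def test_edge_addition_never_increases_distances(self):
        """Monotonicity: adding an edge can only shrink d_s and d_AB."""
        g = random_graph(40, 0.08, seed=9)
        rng = np.random.default_rng(9)
        disease = GeneSet("d", frozenset(rng.choice(g.nodes, 6, replace=False)))
        a = GeneSet("a", frozenset(rng.choice(g.nodes, 5, replace=False)))
        b = GeneSet("b", frozenset(rng.choice(g.nodes, 5, replace=False)))
        before_ds = disease_module_distance(g, disease)["d_s"]
        before_ab = proximity_dAB(g, a, b)["d_ab"]
        g2 = g.graph.copy()
        non_edges = [e for e in nx.non_edges(g2)][:20]
        g2.add_edges_from(non_edges)
        bigger = UnweightedGraph(g2)
        assert disease_module_distance(bigger, disease)["d_s"] <= before_ds
        assert proximity_dAB(bigger, a, b)["d_ab"] <= before_ab


@pytest.fixture(scope="module")
def planted():
    edges, graph, truth = simulate_interactome(
        n_nodes=500, planted_module_sizes=(12,),
        planted_pairs=((10, 10, 1),), seed=21)
    return graph_from_edges(edges), truth


class TestPermutationTests:
    def test_planted_module_significant(self, planted):
        graph, truth = planted
        res = disease_module_significance(
            graph, GeneSet("dm", frozenset(truth.modules["DM1"])),
            n_perm=500, seed=3)
        assert res["p_empirical"] < 0.01 and res["z"] < 0

    def test_zero_permutations_rejected(self, planted):
        graph, truth = planted
        with pytest.raises(ValueError, match="n_perm"):
            disease_module_significance(
                graph, GeneSet("dm", frozenset(truth.modules["DM1"])), n_perm=0)

    def test_identical_graphs_no_day_night_difference(self, planted):
        graph, truth = planted
        res = day_night_module_difference(
            graph, graph, GeneSet("dm", frozenset(truth.modules["DM1"])),
            n_perm=300, seed=4)
        assert res["delta"] == 0.0
        assert res["p_empirical"] > 0.5

    def test_swapping_graphs_negates_delta(self, planted):
        graph, truth = planted
        other = random_graph(400, 0.02, seed=8)
        common = GeneSet("dm", frozenset(
            set(truth.modules["DM1"]) | set(other.nodes[:5])))
        ab = day_night_module_difference(graph, other, common, n_perm=300, seed=5)
        ba = day_night_module_difference(other, graph, common, n_perm=300, seed=5)
        assert ab["delta"] == pytest.approx(-ba["delta"])

    def test_planted_proximal_pair_significant(self, planted):
        graph, truth = planted
        pp = truth.proximal_pairs[0]
        res = proximity_significance(
            graph, GeneSet("a", frozenset(pp["set_a"])),
            GeneSet("b", frozenset(pp["set_b"])), n_perm=500, seed=6)
        assert res["z"] < 0 and res["p_empirical"] < 0.05

    def test_proximity_null_reproducible(self, planted):
        graph, truth = planted
        pp = truth.proximal_pairs[0]
        kw = dict(n_perm=100, seed=11)
        r1 = proximity_significance(graph, GeneSet("a", frozenset(pp["set_a"])),
                                    GeneSet("b", frozenset(pp["set_b"])), **kw)
        r2 = proximity_significance(graph, GeneSet("a", frozenset(pp["set_a"])),
                                    GeneSet("b", frozenset(pp["set_b"])), **kw)
        assert r1["null_mean"] == r2["null_mean"]
        assert r1["p_empirical"] == r2["p_empirical"]

    def test_degree_sampler_preserves_size_and_bins(self, planted):
        graph, _ = planted
        sampler = DegreeBinSampler(graph)
        rng = np.random.default_rng(12)
        template = list(np.asarray(graph.nodes)[rng.choice(graph.n, 15,
                                                           replace=False)])
        for _ in range(10):
            sample = sampler.sample_like(template, rng)
            assert len(sample) == len(template)
            want = sorted(sampler._bin_of[n] for n in template)
            got = sorted(sampler._bin_of[n] for n in sample)
            assert want == got
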