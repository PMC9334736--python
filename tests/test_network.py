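"""Weighted networks: adjacency, fundamental concepts, TOM modules, topology."""

import numpy as np
import pandas as pd
import pytest

from chronet.genesets import GeneSet
from chronet.network import (
    ModuleAssignment,
    WeightedNetwork,
    build_network,
    day_night_topology,
    detect_modules,
    fundamental_concepts,
    module_rhythmicity,
    module_set_enrichment,
    topological_overlap,
    UNASSIGNED,
)
from chronet.simulate import SimulationConfig, simulate_atlas


def brute_force_concepts(a: np.ndarray):
    """Independent loop-based implementation of the six indices."""
    n = len(a)
    k = np.array([sum(a[i, j] for j in range(n) if j != i) for i in range(n)])
    cluster = np.zeros(n)
    mar = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for l in range(n):
                if i != j and i != l and j != l:
                    num += a[i, j] * a[j, l] * a[l, i]
        den = k[i] ** 2 - sum(a[i, j] ** 2 for j in range(n) if j != i)
        cluster[i] = num / den if den > 0 else 0.0
        mar[i] = (sum(a[i, j] ** 2 for j in range(n)) / k[i]) if k[i] > 0 else 0.0
    density = k.sum() / (n * (n - 1))
    centralization = n / (n - 2) * (k.max() / (n - 1) - density)
    heterogeneity = np.sqrt(np.mean((k - k.mean()) ** 2)) / k.mean()
    return k, cluster, mar, density, centralization, heterogeneity


def random_weighted_net(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork([f"g{i}" for i in range(n)], a, beta=1.0)


class TestBuildNetwork:
    def test_perfect_correlation_gives_unit_weight(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        expr = np.stack([x, 3 * x + 1, rng.normal(size=20)])
        net = build_network(expr, ["a", "b", "c"], beta=7.0)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_soft_power_arithmetic(self):
        # cor exactly 0.5 -> weight 0.5^16
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        expr = np.stack([x, x + y])  # cor(x, x+y) = 1/sqrt(2)... build directly
        cor = np.corrcoef(expr)[0, 1]
        net = build_network(expr, ["a", "b"], beta=16.0)
        assert net.adjacency[0, 1] == pytest.approx(abs(cor) ** 16)

    def test_invariants_on_random_data(self):
        rng = np.random.default_rng(1)
        net = build_network(rng.normal(size=(30, 12)),
                            [f"g{i}" for i in range(30)])
        a = net.adjacency
        assert np.allclose(a, a.T)
        assert np.all(np.diag(a) == 0)
        assert a.min() >= 0 and a.max() <= 1

    def test_zero_variance_gene_dropped(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(3, 10))
        expr[1] = 4.2
        net = build_network(expr, ["a", "b", "c"])
        assert net.nodes == ["a", "c"] and net.dropped_zero_variance == ["b"]

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            build_network(np.random.default_rng(0).normal(size=(3, 5)),
                          ["a", "b", "c"], beta=0.5)


class TestFundamentalConcepts:
    def test_complete_unit_graph_closed_forms(self):
        n = 5
        a = np.ones((n, n)) - np.eye(n)
        net = WeightedNetwork([f"g{i}" for i in range(n)], a, beta=1.0)
        nodes, level = fundamental_concepts(net)
        assert np.allclose(nodes["connectivity"], n - 1)
        assert np.allclose(nodes["cluster_coefficient"], 1.0)
        assert np.allclose(nodes["mar"], 1.0)
        assert level["density"] == pytest.approx(1.0)
        assert level["heterogeneity"] == pytest.approx(0.0)
        assert level["centralization"] == pytest.approx(0.0)

    def test_star_graph_hand_computation(self):
        n = 5
        a = np.zeros((n, n))
        a[0, 1:] = a[1:, 0] = 1.0
        net = WeightedNetwork([f"g{i}" for i in range(n)], a, beta=1.0)
        nodes, level = fundamental_concepts(net)
        assert nodes.loc[0, "connectivity"] == 4
        assert np.allclose(nodes.loc[1:, "connectivity"], 1)
        assert level["density"] == pytest.approx(8 / 20)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        net = random_weighted_net(25, seed)
        nodes, level = fundamental_concepts(net)
        k, cluster, mar, density, centr, het = brute_force_concepts(net.adjacency)
        np.testing.assert_allclose(nodes["connectivity"], k, atol=1e-10)
        np.testing.assert_allclose(nodes["cluster_coefficient"], cluster, atol=1e-10)
        np.testing.assert_allclose(nodes["mar"], mar, atol=1e-10)
        assert level["density"] == pytest.approx(density, abs=1e-12)
        assert level["centralization"] == pytest.approx(centr, abs=1e-12)
        assert level["heterogeneity"] == pytest.approx(het, abs=1e-12)

    def test_mar_lower_bound(self):
        """MAR_i >= k_i/(n-1), equality iff incident weights are all equal."""
        net = random_weighted_net(15, 5)
        nodes, _ = fundamental_concepts(net)
        bound = nodes["connectivity"] / (net.n - 1)
        assert np.all(nodes["mar"] >= bound - 1e-12)


class TestModules:
    @staticmethod
    def _block_expression(seed=0, block=40, m=60, cor=0.9):
        """Two planted blocks with strong within-, zero between-correlation."""
        rng = np.random.default_rng(seed)
        lat1, lat2 = rng.normal(size=m), rng.normal(size=m)
        lam = np.sqrt(cor / (1 - cor))
        x1 = lam * lat1 + rng.normal(size=(block, m))
        x2 = lam * lat2 + rng.normal(size=(block, m))
        return np.vstack([x1, x2])

    def test_two_planted_blocks_recovered(self):
        expr = self._block_expression()
        nodes = [f"g{i:03d}" for i in range(80)]
        net = build_network(expr, nodes)
        assign = detect_modules(net, expr)
        mods = assign.modules()
        assert len(mods) == 2
        first = set(assign.members(mods[0]))
        truth_a, truth_b = set(nodes[:40]), set(nodes[40:])
        mis = min(len(first ^ truth_a), len(first ^ truth_b))
        assert mis <= 4  # <= 5% of 80 genes misassigned

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(7)
        expr = rng.normal(size=(100, 40))
        net = build_network(expr, [f"g{i}" for i in range(100)])
        with pytest.warns(UserWarning):
            assign = detect_modules(net, expr)
        frac = (assign.labels == UNASSIGNED).mean()
        assert frac >= 0.95

    def test_rank_one_module_eigengene_is_common_profile(self):
        profile = np.sin(np.linspace(0, 4, 30))
        expr = np.tile(profile, (35, 1))
        expr = expr + 1e-9 * np.random.default_rng(0).normal(size=expr.shape)
        net = build_network(expr, [f"g{i}" for i in range(35)])
        assign = detect_modules(net, expr)
        eig = assign.eigengenes.iloc[:, 0].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        cor = np.corrcoef(eig, z)[0, 1]
        assert abs(cor) > 0.999 and cor > 0  # oriented with the members

    def test_gene_order_invariance_up_to_relabel(self):
        expr = self._block_expression(seed=3)
        nodes = [f"g{i:03d}" for i in range(80)]
        net = build_network(expr, nodes)
        a1 = detect_modules(net, expr)
        rng = np.random.default_rng(1)
        perm = rng.permutation(80)
        net2 = build_network(expr[perm], [nodes[i] for i in perm])
        a2 = detect_modules(net2, expr[perm])
        # canonical comparison: the partition of gene ids must agree
        part1 = {frozenset(a1.members(m)) for m in a1.modules()}
        part2 = {frozenset(a2.members(m)) for m in a2.modules()}
        assert part1 == part2

    def test_tom_range(self):
        net = random_weighted_net(20, 9)
        tom = topological_overlap(net)
        assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)


class TestModuleRhythmicity:
    def test_planted_rhythmic_vs_flat(self, module_study):
        atlas, truth = module_study
        expr = atlas.values.reshape(atlas.n_genes, -1)
        net = build_network(expr, atlas.gene_ids)
        assign = detect_modules(net, expr)
        table = module_rhythmicity(assign, atlas)
        # map detected modules back to planted labels by majority
        planted = pd.Series(truth.module_membership)
        verdict = {}
        for m in assign.modules():
            members = assign.members(m)
            top = planted.reindex(members).mode().iloc[0]
            verdict[top] = table[table["module"] == m]
        rhythmic = verdict["M1"]
        assert rhythmic["is_rhythmic"].all()
        eig_phase = rhythmic[rhythmic["variant"] == "eigengene"]["phase"].iloc[0]
        assert min(abs(eig_phase - 6.0), 24 - abs(eig_phase - 6.0)) <= 2.0
        assert not verdict["M2"]["is_rhythmic"].any()

    def test_single_module_bh_degenerate(self, module_study):
        atlas, _ = module_study
        labels = pd.Series(UNASSIGNED, index=pd.Index(atlas.gene_ids, name="gene"),
                           dtype=object)
        labels.iloc[:30] = "M1"
        expr = atlas.values.reshape(atlas.n_genes, -1)
        from chronet.network import _module_summaries

        eig, mean_x = _module_summaries(expr, atlas.gene_ids, labels)
        assign = ModuleAssignment(labels, eig, mean_x)
        table = module_rhythmicity(assign, atlas)
        np.testing.assert_allclose(table["p_adj"], table["p_raw"])


class TestModuleSetEnrichment:
    def test_perfect_containment(self, module_study):
        atlas, _ = module_study
        expr = atlas.values.reshape(atlas.n_genes, -1)
        net = build_network(expr, atlas.gene_ids)
        assign = detect_modules(net, expr)
        target = assign.modules()[0]
        gene_set = GeneSet("exact", frozenset(assign.members(target)))
        table = module_set_enrichment(assign, gene_set).set_index("module")
        assert table.loc[target, "p"] < 1e-6
        assert table.loc[target, "odds_ratio"] > 10


class TestDayNightTopology:
    def test_planted_night_coupling_detected(self):
        cfg = SimulationConfig(n_genes=150, n_organs=20, seed=31,
                               shared_factor_strength=1.0,
                               night_amplification=0.5)
        atlas, _ = simulate_atlas(cfg)
        per_zt, comparison, _ = day_night_topology(atlas)
        cmp = comparison.set_index("index")
        assert cmp.loc["median_connectivity", "night_minus_day"] > 0
        assert cmp.loc["median_connectivity", "p"] < 0.05
        assert cmp.loc["density", "night_minus_day"] > 0
        assert cmp.loc["density", "p"] < 0.05

    def test_per_zt_isolation(self):
        """Each ZT's network depends only on that ZT's samples."""
        cfg = SimulationConfig(n_genes=60, n_organs=10, seed=32)
        atlas, _ = simulate_atlas(cfg)
        _, _, nets = day_night_topology(atlas)
        import dataclasses

        scrambled = dataclasses.replace(atlas, values=atlas.values.copy())
        scrambled.values[:, :, 1:] = np.random.default_rng(0).permutation(
            scrambled.values[:, :, 1:], axis=2)
        _, _, nets2 = day_night_topology(scrambled)
        np.testing.assert_allclose(nets[0.0].adjacency, nets2[0.0].adjacency)
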