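"""Day/night network comparison: differential connectivity, distances,
weight differences, module Jaccard, hub extraction."""

import numpy as np
import pandas as pd
import pytest

from chronet.compare import (
    differential_connectivity,
    hub_subnetwork,
    module_jaccard,
    node_euclidean_distance,
    pair_weight_difference,
)
from chronet.cycling import detect_global_cycling
from chronet.network import ModuleAssignment, WeightedNetwork, build_network, detect_modules
from chronet.simulate import SimulationConfig, simulate_atlas


def make_net(a, prefix="g"):
    return WeightedNetwork([f"{prefix}{i}" for i in range(len(a))],
                           np.asarray(a, dtype=float), beta=1.0)


@pytest.fixture()
def random_pair():
    rng = np.random.default_rng(0)
    def sym(seed):
        r = np.random.default_rng(seed)
        a = r.uniform(0, 1, (12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a
    return make_net(sym(1)), make_net(sym(2))


class TestDifferentialConnectivity:
    def test_threshold_arithmetic(self):
        a = np.zeros((3, 3)); a[0, 1] = a[1, 0] = 1.0
        b = np.zeros((3, 3)); b[0, 1] = b[1, 0] = 0.4
        table = differential_connectivity(make_net(a), make_net(b)).set_index("gene")
        assert table.loc["g0", "fold"] == pytest.approx(2.5)
        assert table.loc["g0", "is_differential"]

    def test_equal_connectivity_not_differential(self, random_pair):
        net, _ = random_pair
        table = differential_connectivity(net, net)
        assert np.allclose(table["fold"], 1.0)
        assert not table["is_differential"].any()

    def test_swap_preserves_differential_set(self, random_pair):
        net_a, net_b = random_pair
        ab = differential_connectivity(net_a, net_b)
        ba = differential_connectivity(net_b, net_a)
        pd.testing.assert_series_equal(ab["is_differential"], ba["is_differential"])
        np.testing.assert_allclose(ab["fold"], ba["fold"])
        assert (ab["direction"] != ba["direction"]).all() or \
            (ab["k_a"] == ab["k_b"]).any()

    def test_monotone_in_threshold(self, random_pair):
        net_a, net_b = random_pair
        loose = differential_connectivity(net_a, net_b, fold=1.0 + 1e-9)
        tight = differential_connectivity(net_a, net_b, fold=2.0)
        assert set(tight[tight["is_differential"]]["gene"]) <= \
            set(loose[loose["is_differential"]]["gene"])
        # as fold -> 1+, every gene with k_a != k_b becomes differential
        expect = loose["k_a"] != loose["k_b"]
        pd.testing.assert_series_equal(
            loose["is_differential"], expect, check_names=False)

    def test_zero_connectivity_guarded(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3)); b[0, 1] = b[1, 0] = 0.5
        table = differential_connectivity(make_net(a), make_net(b))
        assert table["zero_guarded"].any()
        assert np.isfinite(table["fold"]).all()

    def test_planted_differential_enriched_in_night_coupled_genes(self):
        """With night-amplified shared coupling, per-ZT connectivity shifts
        are widespread, so ZT06-vs-ZT18 differential genes exist."""
        cfg = SimulationConfig(n_genes=100, n_organs=20, seed=61,
                               shared_factor_strength=1.0,
                               night_amplification=0.6)
        atlas, _ = simulate_atlas(cfg)
        t6 = int(np.nonzero(atlas.zt_times == 6.0)[0][0])
        t18 = int(np.nonzero(atlas.zt_times == 18.0)[0][0])
        net6 = build_network(atlas.values[:, :, t6], atlas.gene_ids)
        net18 = build_network(atlas.values[:, :, t18], atlas.gene_ids)
        table = differential_connectivity(net6, net18)
        assert table["is_differential"].mean() > 0.2
        assert (table.loc[table["is_differential"], "direction"] == "B-heavy").mean() > 0.5


class TestNodeEuclidean:
    def test_identical_networks_zero(self, random_pair):
        net, _ = random_pair
        table = node_euclidean_distance(net, net)
        assert np.allclose(table["euclidean_distance"], 0.0)

    def test_single_coordinate_difference(self):
        a = np.zeros((3, 3))
        b = a.copy(); b[0, 1] = b[1, 0] = 0.3
        table = node_euclidean_distance(make_net(a), make_net(b)).set_index("gene")
        assert table.loc["g0", "euclidean_distance"] == pytest.approx(0.3)
        assert table.loc["g1", "euclidean_distance"] == pytest.approx(0.3)
        assert table.loc["g2", "euclidean_distance"] == 0.0

    def test_symmetry(self, random_pair):
        net_a, net_b = random_pair
        ab = node_euclidean_distance(net_a, net_b)["euclidean_distance"]
        ba = node_euclidean_distance(net_b, net_a)["euclidean_distance"]
        np.testing.assert_allclose(ab, ba)

    def test_cyclers_move_more_than_flats(self):
        """Global cyclers change their network neighbourhoods between noon
        and midnight more than arrhythmic genes (phase-modulated coupling
        to the shared organ factor planted)."""
        cfg = SimulationConfig(n_genes=200, n_organs=25, seed=62,
                               cycler_factor_coupling=1.2)
        atlas, truth = simulate_atlas(cfg)
        t6 = int(np.nonzero(atlas.zt_times == 6.0)[0][0])
        t18 = int(np.nonzero(atlas.zt_times == 18.0)[0][0])
        net6 = build_network(atlas.values[:, :, t6], atlas.gene_ids)
        net18 = build_network(atlas.values[:, :, t18], atlas.gene_ids)
        table = node_euclidean_distance(net6, net18).set_index("gene")
        cyc = table.loc[truth.genes_of_class("global_cycler"), "euclidean_distance"]
        flat = table.loc[truth.genes_of_class("flat"), "euclidean_distance"]
        from scipy import stats

        assert cyc.median() > flat.median()
        assert stats.ranksums(cyc, flat).pvalue < 0.05


class TestPairWeightDifference:
    def test_identical_networks_all_zero(self, random_pair):
        net, _ = random_pair
        calls = pd.Series(True, index=net.nodes)
        table = pair_weight_difference(net, net, calls)
        assert table["median_abs_delta"].fillna(0).max() == 0.0

    def test_cycler_pairs_change_weights_more(self):
        """Raw |cor| differences between the noon and midnight networks are
        larger for both-cycler pairs than for flat pairs."""
        cfg = SimulationConfig(n_genes=150, n_organs=25, seed=63,
                               cycler_factor_coupling=1.2)
        atlas, truth = simulate_atlas(cfg)
        t6 = int(np.nonzero(atlas.zt_times == 6.0)[0][0])
        t18 = int(np.nonzero(atlas.zt_times == 18.0)[0][0])
        net6 = build_network(atlas.values[:, :, t6], atlas.gene_ids)
        net18 = build_network(atlas.values[:, :, t18], atlas.gene_ids)
        calls = pd.Series({g: c == "global_cycler"
                           for g, c in truth.gene_class.items()})
        table = pair_weight_difference(net6, net18, calls).set_index("stratum")
        assert table.loc["both", "median_abs_delta"] > \
            table.loc["neither", "median_abs_delta"]
        assert table.attrs["ranksum_both_vs_neither"] < 0.05

    def test_strata_partition_all_pairs(self, random_pair):
        net_a, net_b = random_pair
        rng = np.random.default_rng(3)
        calls = pd.Series(rng.random(net_a.n) < 0.5, index=net_a.nodes)
        table = pair_weight_difference(net_a, net_b, calls)
        n = net_a.n
        assert table["n_pairs"].sum() == n * (n - 1) // 2


class TestModuleJaccard:
    @staticmethod
    def _assignment(groups):
        labels = {}
        for name, members in groups.items():
            for g in members:
                labels[g] = name
        series = pd.Series(labels, dtype=object)
        series.index.name = "gene"
        return ModuleAssignment(series, pd.DataFrame({m: [0.0] for m in groups}),
                                pd.DataFrame({m: [0.0] for m in groups}))

    def test_identical_assignments(self):
        a = self._assignment({"M1": ["a", "b"], "M2": ["c", "d", "e"]})
        table, consensus = module_jaccard(a, a)
        assert np.allclose(np.diag(table.to_numpy()), 1.0)
        assert len(consensus) == 2

    def test_disjoint_modules(self):
        a = self._assignment({"M1": ["a", "b"]})
        b = self._assignment({"M1": ["x", "y"]})
        table, consensus = module_jaccard(a, b)
        assert table.iloc[0, 0] == 0.0 and consensus == []

    def test_planted_shared_blocks_reach_consensus(self, module_study):
        atlas, _ = module_study
        t0 = atlas.values[:, :, [0, 1, 2, 3, 4, 5]].reshape(atlas.n_genes, -1)
        t1 = atlas.values[:, :, [6, 7, 8, 9, 10, 11]].reshape(atlas.n_genes, -1)
        a1 = detect_modules(build_network(t0, atlas.gene_ids), t0)
        a2 = detect_modules(build_network(t1, atlas.gene_ids), t1)
        _, consensus = module_jaccard(a1, a2)
        assert len(consensus) >= 1  # planted blocks persist across scopes


class TestHubSubnetwork:
    def test_small_module_clamps(self):
        net = make_net(np.ones((4, 4)) - np.eye(4))
        assign = TestModuleJaccard._assignment({"M1": ["g0", "g1", "g2"]})
        hubs, induced, scores = hub_subnetwork(net, assign, "M1", top_n=50)
        assert len(hubs) == 3 and induced.shape == (3, 3)

    def test_ties_break_lexicographically(self):
        net = make_net(np.ones((5, 5)) - np.eye(5))
        assign = TestModuleJaccard._assignment(
            {"M1": ["g0", "g1", "g2", "g3", "g4"]})
        hubs, _, _ = hub_subnetwork(net, assign, "M1", top_n=3)
        assert hubs == ["g0", "g1", "g2"]

    def test_scores_match_brute_force(self, random_pair):
        net, _ = random_pair
        members = net.nodes[2:9]
        assign = TestModuleJaccard._assignment({"M1": members})
        _, _, scores = hub_subnetwork(net, assign, "M1", top_n=4)
        idx = {n: i for i, n in enumerate(net.nodes)}
        for _, row in scores.iterrows():
            i = idx[row["gene"]]
            brute = sum(net.adjacency[i, idx[m]] for m in members if m != row["gene"])
            assert row["intramodular_connectivity"] == pytest.approx(brute)

    def test_empty_module_rejected(self, random_pair):
        net, _ = random_pair
        assign = TestModuleJaccard._assignment({"M1": ["g0"]})
        with pytest.raises(ValueError, match="empty"):
            hub_subnetwork(net, assign, "M9")
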