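import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from trisynapse.modularity import (CommunityPartition, ConsensusCommunities,
                                   ModularityParams, align_partitions,
                                   best_partition, composition_regression,
                                   consensus_communities, flexibility,
                                   louvain_signed, modularity_q, module_report,
                                   optimize_gamma, promiscuity,
                                   quintile_profile, rewire_null)
from trisynapse.synthetic import PlantedPartitionSpec, make_planted_partition


def set_partitions(n):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))
    yield from rec([0], 1)


def brute_force_max_q(W, gamma=1.0):
    best = -np.inf
    for labels in set_partitions(W.shape[0]):
        best = max(best, modularity_q(W, labels, gamma))
    return best


class TestQualityFunction:
    def two_cliques(self):
        A = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.permutations(block, 2):
                A[i, j] = 1.0
        return A

    def test_two_cliques_q_half(self):
        A = self.two_cliques()
        labels = np.array([0] * 4 + [1] * 4)
        assert modularity_q(A, labels, 1.0) == pytest.approx(0.5)

    def test_single_module_cancellation(self):
        # sum_ij p_ij = (sum s_out)(sum s_in)/m = m, so gamma = 1 cancels
        A = self.two_cliques()
        gamma = 1.0
        labels = np.zeros(8, dtype=int)
        assert modularity_q(A, labels, gamma) == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        A = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
        np.fill_diagonal(A, 0)
        labels = rng.integers(0, 3, 10)
        q1 = modularity_q(A, labels, 1.3)
        remap = np.array([2, 0, 1])
        assert modularity_q(A, remap[labels], 1.3) == pytest.approx(q1)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            modularity_q(np.zeros((3, 3)), np.array([0, 1]), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_maximizer_matches_enumeration_6_nodes(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((6, 6)) * (rng.random((6, 6)) < 0.5)
        np.fill_diagonal(A, 0)
        found = best_partition(A, 1.0, n_restarts=20, seed=seed).q
        assert found == pytest.approx(brute_force_max_q(A, 1.0), abs=1e-10)


class TestRewiredNull:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_degrees_exactly_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        A = (rng.random((n, n)) < 0.1) * rng.normal(2.0, 0.5, (n, n))
        np.fill_diagonal(A, 0)
        W = sp.csr_matrix(A)
        null = rewire_null(W, seed=seed)
        assert np.array_equal((W != 0).sum(1), (null != 0).sum(1))
        assert np.array_equal((W != 0).sum(0), (null != 0).sum(0))
        assert null.diagonal().sum() == 0

    def test_single_edge_errors(self):
        W = sp.csr_matrix(([1.0], ([0], [1])), shape=(3, 3))
        with pytest.raises(ValueError):
            rewire_null(W)

    def test_null_q_below_empirical_on_planted(self):
        spec = PlantedPartitionSpec(n_nodes=200, n_modules=4, p_in=0.3,
                                    p_out=0.02, seed=5)
        W, labels = make_planted_partition(spec)
        q_emp = modularity_q(W, labels, 1.0)
        null = rewire_null(W, seed=7)
        q_null = best_partition(null, 1.0, 5, seed=1).q
        assert q_null < q_emp


class TestGammaOptimization:
    def test_singleton_sweep(self):
        W, _ = make_planted_partition(PlantedPartitionSpec(n_nodes=60, seed=1))
        g, df = optimize_gamma(W, [1.4], ModularityParams(n_null=2, sweep_runs=2))
        assert g == pytest.approx(1.4)
        assert len(df) == 1

    def test_empty_sweep_errors(self):
        W, _ = make_planted_partition(PlantedPartitionSpec(n_nodes=30, seed=1))
        with pytest.raises(ValueError):
            optimize_gamma(W, [])

    def test_planted_four_modules_recovered_at_selected_gamma(self):
        spec = PlantedPartitionSpec(n_nodes=120, n_modules=4, p_in=0.5,
                                    p_out=0.02, seed=3)
        W, truth = make_planted_partition(spec)
        params = ModularityParams(n_runs=30, n_null=3, sweep_runs=3, seed=0)
        g, _ = optimize_gamma(W, np.arange(0.6, 2.01, 0.2), params)
        part = consensus_communities(W, g, params)
        assert part.n_modules == 4
        assert adjusted_rand_score(truth, part.labels) >= 0.9


class TestConsensus:
    def test_two_cliques_exact(self):
        A = np.zeros((12, 12))
        for block in (range(6), range(6, 12)):
            for i, j in itertools.permutations(block, 2):
                A[i, j] = 1.0
        part = consensus_communities(A, 1.0, ModularityParams(n_runs=50, seed=2))
        assert part.n_modules == 2
        assert adjusted_rand_score([0]*6 + [1]*6, part.labels) == 1.0

    def test_planted_five_modules_strong_contrast(self):
        spec = PlantedPartitionSpec(n_nodes=300, n_modules=5, p_in=0.4,
                                    p_out=0.02, seed=11)
        W, truth = make_planted_partition(spec)
        part = consensus_communities(W, 1.0, ModularityParams(n_runs=50, seed=4))
        assert adjusted_rand_score(truth, part.labels) >= 0.9

    def test_determinism(self):
        W, _ = make_planted_partition(PlantedPartitionSpec(n_nodes=80, seed=6))
        p1 = consensus_communities(W, 1.0, ModularityParams(n_runs=20, seed=9))
        p2 = consensus_communities(W, 1.0, ModularityParams(n_runs=20, seed=9))
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    def test_clusterer_interface(self):
        W, truth = make_planted_partition(
            PlantedPartitionSpec(n_nodes=90, n_modules=3, p_in=0.5,
                                 p_out=0.02, seed=2))
        est = ConsensusCommunities(gamma_res=1.0, n_runs=30, seed=1)
        labels = est.fit_predict(W)
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert est.get_params()["n_runs"] == 30


class TestModuleReport:
    def _meta(self, regions, inhibitory):
        return pd.DataFrame({"region": regions,
                             "excitatory": ~np.asarray(inhibitory)})

    def test_single_module_range_zero(self):
        meta = self._meta(["CA3"] * 5, [False] * 5)
        _, summary = module_report(np.zeros(5, dtype=int), meta)
        assert summary["size_range"] == 0
        assert summary["n_modules"] == 1

    def test_composition_counting_oracle(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        meta = self._meta(["CA3", "CA3", "CA1", "CA1", "CA1", "CA1", "CA3"],
                          [False, True, False, False, False, True, True])
        df, _ = module_report(labels, meta)
        m0 = df.set_index("module").loc[0]
        assert m0["size"] == 3
        assert m0["pct_ca3"] == pytest.approx(100 * 2 / 3)
        assert m0["pct_inhibitory"] == pytest.approx(100 * 1 / 3)

    def test_size_range(self):
        labels = np.array([0] * 100 + [1] * 350)
        meta = self._meta(["CA3"] * 450, [False] * 450)
        _, summary = module_report(labels, meta)
        assert summary["size_range"] == 250


class TestCompositionRegression:
    def test_perfect_collinearity(self):
        t = pd.DataFrame({"pct_inhibitory": [1, 2, 3, 4.0],
                          "pct_ca1": [2, 4, 6, 8.0]})
        res = composition_regression(t)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.1, 2.9, 6.2, 7.4, 10.0])
        t = pd.DataFrame({"pct_inhibitory": x, "pct_ca1": y})
        res = composition_regression(t)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["slope"] == pytest.approx(beta[0])
        assert res["intercept"] == pytest.approx(beta[1])

    def test_uncorrelated_low_r2(self, rng):
        t = pd.DataFrame({"pct_inhibitory": rng.random(200),
                          "pct_ca1": rng.random(200)})
        assert composition_regression(t)["r2"] < 0.05

    def test_degenerate_x_errors(self):
        t = pd.DataFrame({"pct_inhibitory": [1.0, 1.0, 1.0],
                          "pct_ca1": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            composition_regression(t)


class TestDynamics:
    def test_identical_partitions_zero_flexibility(self):
        p = np.array([0, 0, 1, 1, 2])
        assert np.all(flexibility([p, p, p, p]) == 0.0)

    def test_alternating_node_max_flexibility(self):
        # node 4 hops between two stable blocks every timepoint
        a = np.array([0, 0, 1, 1, 0])
        b = np.array([0, 0, 1, 1, 1])
        flex = flexibility([a, b, a, b, a])
        assert flex[4] == pytest.approx(1.0)
        assert np.all(flex[:4] == 0.0)

    def test_flexibility_counting_oracle(self):
        # stable blocks with planned switches; alignment is unambiguous
        seq = [np.array([0, 0, 0, 1, 1, 1]),
               np.array([0, 0, 1, 1, 1, 1]),
               np.array([0, 0, 1, 1, 1, 0])]
        flex = flexibility(seq)
        expected = np.array([0, 0, 1, 0, 0, 1]) / 2.0
        assert np.allclose(flex, expected)

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError):
            flexibility([np.array([0, 1])])

    def test_promiscuity_single_community_floor(self):
        a = np.array([0, 0, 1, 1])
        prom = promiscuity([a, a, a])
        assert np.allclose(prom, 0.5)  # each node joins 1 of 2 communities

    def test_flexible_but_not_promiscuous(self):
        # node 8 alternates between 2 of the 5 available communities
        base = np.array([0, 0, 1, 1, 2, 2, 3, 3, 0])
        alt = base.copy()
        alt[8] = 1
        seq = [base, alt, base, alt, base]
        flex = flexibility(seq)
        prom = promiscuity(seq)
        assert flex[8] == pytest.approx(1.0)
        assert prom[8] == pytest.approx(2 / 4)
        assert prom[8] < 1.0

    def test_promiscuity_counting_oracle(self, rng):
        seq = [rng.integers(0, 3, 12) for _ in range(6)]
        aligned = align_partitions(seq)
        stack = np.stack(aligned)
        total = len(np.unique(stack))
        prom = promiscuity(seq)
        for i in range(12):
            assert prom[i] == pytest.approx(len(np.unique(stack[:, i])) / total)


class TestQuintiles:
    def test_uniform_occupancy(self, rng):
        vals = rng.random(5000)
        prof = quintile_profile(vals, np.zeros(5000, dtype=int))
        assert np.allclose(prof.loc[0].to_numpy(), 0.2, atol=0.02)

    def test_extreme_group_elevated_tails(self, rng):
        off = rng.normal(0, 1, 1000)
        tgt = np.concatenate([rng.normal(-4, 0.2, 100), rng.normal(4, 0.2, 100)])
        vals = np.concatenate([off, tgt])
        groups = np.array(["off"] * 1000 + ["target"] * 200)
        prof = quintile_profile(vals, groups)
        assert prof.loc["target", "q1"] + prof.loc["target", "q5"] > 0.9

    def test_boundaries_match_sorting(self):
        vals = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5])
        prof = quintile_profile(vals, np.zeros(10, dtype=int))
        assert prof.loc[0].sum() == pytest.approx(1.0)
        assert np.allclose(prof.loc[0].to_numpy(), 0.2)

    def test_too_few_nodes_errors(self):
        with pytest.raises(ValueError):
            quintile_profile(np.array([1.0, 2.0]), np.array([0, 0]))
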