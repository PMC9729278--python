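import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from trisynapse.separation import (hamming_distance, membership_vector,
                                   normalize_responses, percent_overlap,
                                   population_distance_delta, select_targets,
                                   separation_report, snr, spearman_distance)
from trisynapse.synthetic import SyntheticResponseSpec, make_response_tables


def _table(neurons, responses, region="CA1", pattern="P1"):
    return pd.DataFrame({"neuron": neurons, "region": region,
                         "pattern": pattern, "response": responses})


class TestNormalization:
    def test_identity_gives_ones(self):
        t = _table([0, 1, 2], [1.0, 2.0, 3.0])
        out = normalize_responses(t, t, epsilon=0.01)
        assert np.allclose(out["normalized"], 1.0)

    def test_simple_ratio(self):
        u = _table([0], [2.0])
        t = _table([0], [6.0])
        out = normalize_responses(t, u, epsilon=0.0)
        assert out["normalized"].iloc[0] == pytest.approx(3.0)

    def test_silent_untrained_neuron_finite(self):
        u = _table([0, 1], [0.0, 2.0])
        t = _table([0, 1], [4.0, 2.0])
        out = normalize_responses(t, u, epsilon=1.0 / 360)
        assert np.all(np.isfinite(out["normalized"]))
        assert out["normalized"].iloc[0] == pytest.approx((4 + 1/360) / (1/360))

    def test_mismatched_sets_error(self):
        with pytest.raises(ValueError):
            normalize_responses(_table([0, 1], [1, 1]), _table([0, 2], [1, 1]), 0.1)


class TestTargetSelection:
    def _norm(self, rates, region="CA1"):
        return pd.DataFrame({"neuron": np.arange(len(rates)), "region": region,
                             "pattern": "P1", "normalized": rates})

    def test_decreasing_rates_select_prefix(self):
        norm = self._norm(np.arange(50, 0, -1, dtype=float))
        a = select_targets(norm, 10, {"CA1": np.arange(50)})
        assert np.array_equal(a.targets[("CA1", "P1")], np.arange(10))

    def test_all_equal_ties_lowest_indices(self):
        norm = self._norm(np.ones(30))
        a = select_targets(norm, 5, {"CA1": np.arange(30)})
        assert np.array_equal(a.targets[("CA1", "P1")], np.arange(5))

    def test_matches_sort_oracle(self, rng):
        rates = rng.random(200)
        norm = self._norm(rates)
        a = select_targets(norm, 40, {"CA1": np.arange(200)})
        oracle = np.sort(np.argsort(-rates, kind="stable")[:40])
        assert np.array_equal(a.targets[("CA1", "P1")], oracle)

    def test_additive_shift_invariance(self, rng):
        rates = rng.random(100)
        a = select_targets(self._norm(rates), 20, {"CA1": np.arange(100)})
        b = select_targets(self._norm(rates + 7.3), 20, {"CA1": np.arange(100)})
        assert np.array_equal(a.targets[("CA1", "P1")], b.targets[("CA1", "P1")])

    def test_excluded_inputs_not_selected(self, rng):
        rates = rng.random(100)
        excluded = np.arange(0, 100, 2)
        a = select_targets(self._norm(rates), 20, {"CA1": np.arange(100)},
                           excluded=excluded)
        assert np.intersect1d(a.targets[("CA1", "P1")], excluded).size == 0

    def test_too_few_eligible_errors(self):
        with pytest.raises(ValueError):
            select_targets(self._norm(np.ones(10)), 10, {"CA1": np.arange(10)})


class TestSNR:
    def test_hand_computed(self):
        norm = pd.DataFrame({
            "neuron": [0, 1, 2, 3], "region": "CA1", "pattern": "P1",
            "normalized": [4.0, 4.0, 2.0, 2.0]})
        from trisynapse.separation import TargetAssignment
        a = TargetAssignment({("CA1", "P1"): np.array([0, 1])},
                             {("CA1", "P1"): np.array([2, 3])}, 2)
        out = snr(a, norm)
        assert out["snr"].iloc[0] == pytest.approx(2.0)


class TestSetMetrics:
    def test_overlap_examples(self):
        a = np.arange(200)
        assert percent_overlap(a, a) == 100.0
        assert percent_overlap(a, a + 500) == 0.0
        b = np.concatenate([np.arange(100), np.arange(1000, 1100)])
        assert percent_overlap(a, b) == 50.0

    def test_overlap_size_mismatch(self):
        with pytest.raises(ValueError):
            percent_overlap(np.arange(3), np.arange(4))

    def test_hamming_examples(self):
        assert hamming_distance([1, 1, 0, 0], [1, 1, 0, 0]) == 0.0
        assert hamming_distance([1, 0, 1], [0, 1, 0]) == 1.0
        assert hamming_distance([1, 1, 0, 0], [1, 0, 1, 0]) == 0.5

    def test_hamming_mismatch(self):
        with pytest.raises(ValueError):
            hamming_distance([1, 0], [1, 0, 1])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**16 - 1))
    def test_hamming_brute_force(self, bits):
        x = np.array([(bits >> i) & 1 for i in range(16)])
        y = np.roll(x, 3)
        assert hamming_distance(x, y) == np.mean(x != y)


class TestPopulationDistance:
    def test_identical_outputs_zero_delta(self):
        ref = np.arange(50)
        out = population_distance_delta(np.arange(10), np.arange(5, 15),
                                        np.arange(10), np.arange(5, 15),
                                        ref, ref)
        assert out["pd_delta"] == 0.0

    def test_disjoint_outputs_positive(self):
        ref = np.arange(100)
        out = population_distance_delta(
            np.arange(20), np.arange(10, 30),          # 50% input overlap
            np.arange(20), np.arange(40, 60), ref, ref)  # disjoint outputs
        assert out["pd_delta"] > 0

    def test_enumeration_oracle(self):
        in_ref = np.arange(8)
        out_ref = np.arange(6)
        ia, ib = np.array([0, 1, 2]), np.array([2, 3, 4])
        oa, ob = np.array([0, 1]), np.array([1, 2])
        res = population_distance_delta(ia, ib, oa, ob, in_ref, out_ref)
        d_in = sum(1 for j in in_ref if (j in ia) != (j in ib)) / 8
        d_out = sum(1 for j in out_ref if (j in oa) != (j in ob)) / 6
        assert res["d_in"] == pytest.approx(d_in)
        assert res["d_out"] == pytest.approx(d_out)
        assert res["pd_delta"] == pytest.approx(d_out - d_in)

    def test_member_outside_reference_errors(self):
        with pytest.raises(ValueError):
            population_distance_delta(np.array([99]), np.array([1]),
                                      np.array([0]), np.array([1]),
                                      np.arange(10), np.arange(10))

    def test_lower_overlap_increases_distance(self):
        ref = np.arange(100)
        a = np.arange(20)
        d = []
        for shift in (5, 10, 15, 20):
            b = np.arange(shift, shift + 20)
            d.append(hamming_distance(membership_vector(a, ref),
                                      membership_vector(b, ref)))
        assert all(x < y for x, y in zip(d, d[1:]))


class TestSpearmanDistance:
    def test_identical_zero(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        assert spearman_distance(x, x) == pytest.approx(0.0)

    def test_reversed_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_distance(x, x[::-1]) == pytest.approx(2.0)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            x, y = rng.random(15), rng.random(15)
            rho = sps.spearmanr(x, y).statistic
            assert spearman_distance(x, y) == pytest.approx(1 - rho)

    def test_symmetry(self, rng):
        x, y = rng.random(10), rng.random(10)
        assert spearman_distance(x, y) == pytest.approx(spearman_distance(y, x))

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman_distance(np.ones(5), np.arange(5.0))

    def test_range_bounds(self, rng):
        for _ in range(50):
            sd = spearman_distance(rng.random(8), rng.random(8))
            assert 0.0 <= sd <= 2.0


class TestSeparationReport:
    def test_planted_disjoint_targets_zero_overlap(self):
        spec = SyntheticResponseSpec(neurons_per_region=200, n_targets=20,
                                     effect_size=8.0, noise_sd=0.05,
                                     target_overlap=0.0, seed=3)
        untrained, trained, truth = make_response_tables(spec)
        norm = normalize_responses(trained, untrained, 1e-3)
        eligible = {r: norm[norm["region"] == r]["neuron"].unique()
                    for r in spec.regions}
        a = select_targets(norm, 20, eligible)
        rep = separation_report(a, norm,
                                {"P1": truth[("DG", "P1")],
                                 "P2": truth[("DG", "P2")]},
                                eligible["DG"], eligible)
        dg = rep.per_region.set_index("region").loc["DG"]
        assert dg["overlap_pct"] == 0.0

    def test_symmetric_inputs_give_equal_pattern_metrics(self):
        neurons = np.arange(40)
        rows = []
        for pattern in ("P1", "P2"):
            rows.append(pd.DataFrame({
                "neuron": neurons, "region": "CA1", "pattern": pattern,
                "normalized": np.where(neurons < 10, 5.0, 1.0)}))
        norm = pd.concat(rows, ignore_index=True)
        a = select_targets(norm, 10, {"CA1": neurons})
        table = snr(a, norm)
        s1 = table[table["pattern"] == "P1"]["snr"].iloc[0]
        s2 = table[table["pattern"] == "P2"]["snr"].iloc[0]
        assert s1 == pytest.approx(s2)

    def test_report_deterministic(self):
        spec = SyntheticResponseSpec(seed=9)
        u, t, truth = make_response_tables(spec)
        norm = normalize_responses(t, u, 1e-3)
        eligible = {r: norm[norm["region"] == r]["neuron"].unique()
                    for r in spec.regions}
        reps = []
        for _ in range(2):
            a = select_targets(norm, spec.n_targets, eligible)
            rep = separation_report(a, norm,
                                    {"P1": truth[("DG", "P1")],
                                     "P2": truth[("DG", "P2")]},
                                    eligible["DG"], eligible)
            reps.append(rep.per_region)
        pd.testing.assert_frame_equal(reps[0], reps[1])
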