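import math

import numpy as np
import pandas as pd
import pytest

from quantalglu import (
    QuantalSeries,
    bin_events,
    count_per_cycle,
    estimate_distributions,
    information_rate,
    make_stimulus,
    mutual_information,
    snr,
    specific_information,
)
from quantalglu.info import InfoDistributions, information_report, shuffle_null_information
from quantalglu.response import CyclewiseCounts


def mutual_information_oracle(p_sq, p_s, p_q):
    """Brute-force double sum of the mutual-information definition."""
    total = 0.0
    for i in range(p_sq.shape[0]):
        for j in range(p_sq.shape[1]):
            if p_sq[i, j] > 0:
                total += p_sq[i, j] * math.log2(p_sq[i, j] / (p_s[i] * p_q[j]))
    return total


def random_dists(rng, n_s=4, n_q=4):
    cond = rng.dirichlet(np.ones(n_q), size=n_s)
    p_s = rng.dirichlet(np.ones(n_s))
    return InfoDistributions.from_conditional(cond, p_s)


def _counts(vesicles_by_contrast, frequency=5.0):
    rows = []
    i = 0
    for c, vals in vesicles_by_contrast.items():
        for v in vals:
            rows.append({"cycle": i, "contrast": c, "events": int(v > 0),
                         "vesicles": v, "mean_event_amplitude": np.nan})
            i += 1
    return CyclewiseCounts(table=pd.DataFrame(rows), frequency=frequency)


class TestSNR:
    def test_two_trial_closed_form(self):
        res = snr(_counts({60.0: [2, 4]}))
        row = res.table.iloc[0]
        assert row["S"] == 3.0
        assert row["sigma2"] == 2.0  # unbiased (n-1) estimator
        assert row["snr"] == pytest.approx(4.5)

    def test_constant_counts_flagged_infinite(self):
        res = snr(_counts({60.0: [3, 3, 3, 3]}))
        row = res.table.iloc[0]
        assert row["infinite"]
        assert np.isinf(row["snr"])

    def test_scale_invariance(self):
        a = snr(_counts({60.0: [2, 4, 7, 3]})).table["snr"].iloc[0]
        b = snr(_counts({60.0: [6, 12, 21, 9]})).table["snr"].iloc[0]
        assert a == pytest.approx(b)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match=">= 2 trials"):
            snr(_counts({60.0: [2]}))


class TestBinEvents:
    def test_event_quanta_land_in_their_bin(self):
        p = make_stimulus([50.0], frequency=5.0, repeats=1, seed=0)
        s = QuantalSeries(times=np.array([0.03]), quanta=np.array([2]))
        binned = bin_events(s, p, bin_width=0.02)
        assert binned.q.tolist() == [0, 2, 0, 0, 0, 0, 0, 0, 0, 0]
        assert binned.violations.size == 0

    def test_ten_bins_per_200ms_cycle(self, protocol11):
        s = QuantalSeries(times=np.empty(0), quanta=np.empty(0, int))
        binned = bin_events(s, protocol11, bin_width=0.02)
        assert binned.bins_per_cycle == 10
        assert binned.n_bins == 10 * protocol11.n_cycles

    def test_double_occupancy_summed_and_flagged(self):
        p = make_stimulus([50.0], frequency=5.0, repeats=1, seed=0)
        s = QuantalSeries(times=np.array([0.030, 0.035]), quanta=np.array([1, 2]))
        binned = bin_events(s, p, bin_width=0.02)
        assert binned.q[1] == 3
        assert binned.violations.tolist() == [1]
        assert binned.violation_rate == pytest.approx(0.1)

    def test_nondividing_width_rejected_with_suggestions(self, protocol11):
        s = QuantalSeries(times=np.empty(0), quanta=np.empty(0, int))
        with pytest.raises(ValueError, match="does not divide"):
            bin_events(s, protocol11, bin_width=0.03)


class TestEstimateDistributions:
    def test_degenerate_single_contrast(self):
        p = make_stimulus([50.0], frequency=5.0, repeats=3, seed=0)
        s = QuantalSeries(times=np.empty(0), quanta=np.empty(0, int))
        dists = estimate_distributions(bin_events(s, p), p)
        assert dists.p_q_given_s[0, 0] == 1.0
        dists.validate()

    def test_hand_worked_two_by_two(self):
        # 2 contrasts x 5 cycles x 10 bins = 50 bins per contrast.
        # contrast 20: 10 bins hold one quantum; contrast 60: 25 bins do.
        p = make_stimulus([20.0, 60.0], frequency=5.0, repeats=5, seed=0, randomize=False)
        edges = p.cycle_edges
        t20 = np.concatenate([edges[i] + 0.02 * np.arange(2) + 0.001 for i in range(5)])
        t60 = np.concatenate([edges[5 + i] + 0.02 * np.arange(5) + 0.001 for i in range(5)])
        times = np.sort(np.concatenate([t20, t60]))
        s = QuantalSeries(times=times, quanta=np.ones(times.size, int))
        dists = estimate_distributions(bin_events(s, p), p)
        # manual arithmetic
        assert dists.p_q_given_s[0].tolist() == pytest.approx([0.8, 0.2])
        assert dists.p_q_given_s[1].tolist() == pytest.approx([0.5, 0.5])
        assert dists.p_sq[0].tolist() == pytest.approx([0.4, 0.1])
        assert dists.p_sq[1].tolist() == pytest.approx([0.25, 0.25])
        assert dists.p_q.tolist() == pytest.approx([0.65, 0.35])
        assert dists.p_s_given_q[:, 1].tolist() == pytest.approx(
            [0.1 / 0.35, 0.25 / 0.35]
        )
        dists.validate()

    def test_conditional_rows_always_normalized(self, protocol11, mvr_model):
        from quantalglu import simulate_release

        s = simulate_release(protocol11, mvr_model, seed=5)
        dists = estimate_distributions(bin_events(s, protocol11), protocol11)
        assert np.allclose(dists.p_q_given_s.sum(axis=1), 1.0)
        dists.validate()


class TestMutualInformation:
    def test_independent_variables_carry_zero_bits(self):
        cond = np.tile([0.7, 0.3], (5, 1))
        d = InfoDistributions.from_conditional(cond, np.full(5, 0.2))
        assert mutual_information(d) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_bijection_over_eleven_stimuli(self):
        d = InfoDistributions.from_conditional(np.eye(11), np.full(11, 1 / 11))
        assert mutual_information(d) == pytest.approx(np.log2(11))
        assert round(mutual_information(d), 2) == 3.46

    def test_binary_symmetric_channel_closed_form(self):
        flip = 0.25
        cond = np.array([[1 - flip, flip], [flip, 1 - flip]])
        d = InfoDistributions.from_conditional(cond, np.array([0.5, 0.5]))
        h_b = -(flip * np.log2(flip) + (1 - flip) * np.log2(1 - flip))
        assert mutual_information(d) == pytest.approx(1.0 - h_b)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            d = random_dists(rng)
            assert mutual_information(d) == pytest.approx(
                mutual_information_oracle(d.p_sq, d.p_s, d.p_q), abs=1e-12
            )

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            d = random_dists(rng, n_s=5, n_q=3)
            i = mutual_information(d)
            h = lambda p: -np.sum(p[p > 0] * np.log2(p[p > 0]))
            assert -1e-12 <= i <= min(h(d.p_s), h(d.p_q)) + 1e-12

    def test_coarse_graining_never_increases_information(self):
        # data-processing: merging two response symbols cannot add bits
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = random_dists(rng, n_s=4, n_q=4)
            merged = np.column_stack(
                [d.p_q_given_s[:, 0] + d.p_q_given_s[:, 1], d.p_q_given_s[:, 2:]]
            )
            dm = InfoDistributions.from_conditional(merged, d.p_s)
            assert mutual_information(dm) <= mutual_information(d) + 1e-12


class TestSpecificInformation:
    def test_deterministic_channel_pins_down_stimulus(self):
        d = InfoDistributions.from_conditional(np.eye(11), np.full(11, 1 / 11))
        i2 = specific_information(d)
        assert np.allclose(i2["i2_bits"], np.log2(11))

    def test_uninformative_symbol_carries_zero(self):
        cond = np.tile([0.5, 0.5], (4, 1))
        d = InfoDistributions.from_conditional(cond, np.full(4, 0.25))
        i2 = specific_information(d)
        assert np.allclose(i2["i2_bits"], 0.0, atol=1e-12)

    def test_weighted_mean_equals_mutual_information(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = random_dists(rng)
            i2 = specific_information(d)
            total = float((i2["p_q"] * i2["i2_bits"]).sum())
            assert total == pytest.approx(mutual_information(d), abs=1e-9)


class TestEstimatorConvergence:
    def test_plugin_bias_shrinks_with_sample_size(self):
        # known channel: plug-in I approaches the true I as bins grow,
        # with the documented positive small-sample bias
        rng = np.random.default_rng(4)
        cond = np.array(
            [
                [0.70, 0.20, 0.10],
                [0.45, 0.35, 0.20],
                [0.25, 0.45, 0.30],
                [0.10, 0.40, 0.50],
            ]
        )
        p_s = np.full(4, 0.25)
        true_i = mutual_information(InfoDistributions.from_conditional(cond, p_s))
        biases = []
        for n_bins, n_reps in ((100, 400), (1000, 200), (10000, 100)):
            reps = []
            for _ in range(n_reps):
                emp = np.stack([rng.multinomial(n_bins, row) / n_bins for row in cond])
                reps.append(
                    mutual_information(InfoDistributions.from_conditional(emp, p_s))
                )
            biases.append(np.mean(reps) - true_i)
        assert abs(biases[0]) > abs(biases[1]) > abs(biases[2])  # |bias| shrinks
        assert all(b > 0 for b in biases)  # plug-in bias is positive


class TestInformationReport:
    def test_rate_conversion_and_bin_budget(self, protocol11, mvr_model):
        from quantalglu import simulate_release

        s = simulate_release(protocol11, mvr_model, seed=31)
        counts = count_per_cycle(s, protocol11)
        rep = information_report(s, protocol11, counts=counts)
        assert rep.h_s_bits == pytest.approx(np.log2(11))
        assert rep.bits_per_cycle == pytest.approx(rep.mi_bits_per_bin * 10)
        assert rep.bits_per_s == pytest.approx(rep.bits_per_cycle * 5)
        assert rep.snr is not None

    def test_cycle_symbol_alternative_is_bounded_by_stimulus_entropy(
        self, protocol11, mvr_model
    ):
        from quantalglu import simulate_release

        s = simulate_release(protocol11, mvr_model, seed=37)
        rep = information_report(s, protocol11, cycle_information="cycle_symbols")
        assert 0 <= rep.bits_per_cycle <= np.log2(11) + 1e-12

    def test_shuffle_null_sits_at_plugin_bias_scale(self, protocol11, mvr_model):
        from quantalglu import simulate_release

        s = simulate_release(protocol11, mvr_model, seed=41)
        binned = bin_events(s, protocol11)
        null = shuffle_null_information(binned, protocol11, n_shuffles=20, seed=0)
        assert np.all(null >= 0)
        assert null.mean() < 0.3  # far below H(S)


def test_information_rate_requires_positive_frequency():
    with pytest.raises(ValueError):
        information_rate(1.0, 0.0)
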