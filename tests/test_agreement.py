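"""Confusion statistics, FiO2 binning, oximetry error analyses."""

import numpy as np
import pytest

from sfpf.agreement import (ConfusionMatrix, accuracy_and_recall,
                            bias_precision, binned_bias_profile, confusion,
                            curve_deviation, direction_rates,
                            fio2_bin_center, fio2_binned_accuracy, pearson_r)
from sfpf.classification import Severity
from sfpf.physiology import severinghaus_sao2

NONE, MILD, MOD, SEV = Severity


class TestConfusion:
    def test_identical_labels_diagonal(self):
        m = confusion([MILD, SEV, MOD], [MILD, SEV, MOD])
        assert np.trace(m.counts) == 3 == m.total

    def test_off_diagonal_cell(self):
        m = confusion([MILD, SEV], [MOD, SEV])
        assert m.counts[MILD, MOD] == 1 and m.counts[SEV, SEV] == 1

    def test_empty_matrix_accuracy_errors(self):
        m = confusion([], [])
        assert m.total == 0
        with pytest.raises(ValueError):
            accuracy_and_recall(m)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([MILD], [MILD, SEV])

    def test_marginals_reproduce_frequencies(self):
        ref = [SEV, SEV, MOD, MILD, NONE, MOD]
        test = [SEV, MOD, MOD, MILD, MILD, SEV]
        m = confusion(ref, test)
        assert m.counts.sum(axis=1).tolist() == [ref.count(c) for c in Severity]
        assert m.counts.sum(axis=0).tolist() == [test.count(c) for c in Severity]


class TestAccuracyRecallDirections:
    def test_diagonal_perfect(self):
        m = confusion([SEV, MOD], [SEV, MOD])
        overall, recall = accuracy_and_recall(m)
        assert overall == 1.0
        assert recall[SEV] == 1.0 and recall[NONE] is None  # empty row absent

    def test_mixed_counts(self):
        ref = [SEV] * 6 + [MOD] * 4
        test = [SEV] * 6 + [MILD] * 4
        overall, _ = accuracy_and_recall(confusion(ref, test))
        assert overall == pytest.approx(0.6)

    def test_direction_rates_worked_example(self):
        # 3 over, 1 under, 6 diagonal
        ref = [MOD] * 3 + [MOD] + [MILD] * 6
        test = [SEV] * 3 + [MILD] + [MILD] * 6
        over, under, share = direction_rates(confusion(ref, test))
        assert (over, under) == (0.3, 0.1)
        assert share == pytest.approx(0.75)

    def test_transpose_swaps_directions(self):
        rng = np.random.default_rng(1)
        ref = rng.integers(0, 4, 50)
        test = rng.integers(0, 4, 50)
        m = confusion(ref, test)
        over, under, _ = direction_rates(m)
        mt = ConfusionMatrix(counts=m.counts.T)
        over_t, under_t, _ = direction_rates(mt)
        assert (over, under) == (under_t, over_t)

    def test_conservation_identity(self):
        rng = np.random.default_rng(2)
        m = confusion(rng.integers(0, 4, 200), rng.integers(0, 4, 200))
        overall, _ = accuracy_and_recall(m)
        over, under, _ = direction_rates(m)
        n_over = int(np.triu(m.counts, 1).sum())
        n_under = int(np.tril(m.counts, -1).sum())
        assert n_over + n_under + int(np.trace(m.counts)) == m.total
        assert over + under + overall == pytest.approx(1.0)


class TestFio2Bins:
    @pytest.mark.parametrize("fio2,center", [
        (0.675, 70.0), (0.674, 65.0), (0.50, 50.0), (0.21, 20.0), (1.0, 100.0)])
    def test_edge_rule(self, fio2, center):
        assert fio2_bin_center(fio2) == center

    def test_single_bin_all_concordant(self):
        bins = fio2_binned_accuracy([0.5] * 5, [MOD] * 5, [MOD] * 5)
        assert bins == [(50.0, 5, 1.0)]

    def test_pooled_accuracy_is_weighted_bin_mean(self):
        rng = np.random.default_rng(3)
        fio2 = rng.uniform(0.21, 1.0, 300)
        ref = rng.integers(0, 4, 300)
        test = rng.integers(0, 4, 300)
        bins = fio2_binned_accuracy(fio2, ref, test)
        pooled, _ = accuracy_and_recall(confusion(ref, test))
        weighted = sum(n * a for _, n, a in bins) / sum(n for _, n, a in bins)
        assert weighted == pytest.approx(pooled)


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(pearson_r(rng.normal(size=10000), rng.normal(size=10000))) < 0.05

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOximetry:
    def test_bias_precision_worked_values(self):
        assert bias_precision([95.0, 95.0], [95.0, 95.0]) == (0.0, 0.0)
        bias, sd = bias_precision([96.0, 94.0], [95.0, 95.0])
        assert bias == 0.0 and sd == pytest.approx(np.sqrt(2), abs=1e-6)
        with pytest.raises(ValueError):
            bias_precision([95.0], [95.0])

    def test_constant_bias_no_crossing(self):
        rng = np.random.default_rng(5)
        sao2 = rng.uniform(85, 99, 200)
        profile, crossing = binned_bias_profile(sao2 + 1.0, sao2)
        assert crossing is None
        assert all(b == pytest.approx(1.0) for _, _, b in profile)

    def test_negating_bias_negates_profile(self):
        rng = np.random.default_rng(6)
        sao2 = rng.uniform(85, 99, 500)
        spo2 = sao2 + rng.normal(0, 1, 500)
        prof_pos, _ = binned_bias_profile(spo2, sao2)
        prof_neg, _ = binned_bias_profile(-spo2, -sao2)
        neg_map = {-c: -b for c, _, b in prof_neg}
        for c, _, b in prof_pos:
            assert neg_map[c] == pytest.approx(b)

    def test_curve_exact_deviation_zero(self):
        pao2 = np.linspace(40, 120, 50)
        assert curve_deviation(pao2, severinghaus_sao2(pao2)) == 0.0

    def test_added_noise_sets_rms(self):
        rng = np.random.default_rng(7)
        pao2 = np.linspace(40, 120, 20000)
        noisy = severinghaus_sao2(pao2) + rng.normal(0, 0.02, pao2.size)
        assert curve_deviation(pao2, noisy) == pytest.approx(0.02, rel=0.05)

    def test_sao2_follows_curve_better_than_spo2(self, minute_admission):
        from sfpf.matching import build_datapoints
        dps = [d for d in build_datapoints(minute_admission)
               if d.spo2 is not None and d.sao2 is not None]
        pao2 = [d.pao2 for d in dps]
        rms_sao2 = curve_deviation(pao2, [d.sao2 for d in dps])
        rms_spo2 = curve_deviation(pao2, [d.spo2 / 100.0 for d in dps])
        assert rms_sao2 < rms_spo2
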