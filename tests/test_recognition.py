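"""Windowing, splitting, standardisation, SVM scoring and KS statistics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from loosewear import (
    ActivityRecognition,
    ClassifierConfig,
    DatasetSpec,
    TrajectoryDataset,
    WindowSet,
    empirical_ks,
    generate_dataset,
    ks_distance_fabric,
    paired_accuracy_comparison,
    segment_windows,
    split_train_test,
    train_and_evaluate,
    zscore_standardize,
)
from loosewear.distributions import FabricPositionDistribution


def brute_force_ks(a, b):
    """Double-loop ECDF supremum, the independent oracle."""
    pool = np.concatenate([a, b])
    return max(abs((a <= v).mean() - (b <= v).mean()) for v in pool)


def make_windows(X, labels, window_len=None):
    X = np.asarray(X, dtype=float)
    wl = X.shape[1] if window_len is None else window_len
    return WindowSet(X, np.asarray(labels), np.arange(len(X)), wl)


class TestSegmentWindows:
    def test_stride_one_pattern(self):
        ws = segment_windows(np.array([1.0, 2, 3, 4, 5]), 3)
        np.testing.assert_array_equal(
            ws.windows, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])

    def test_full_length_window_is_whole_trajectory(self):
        x = np.arange(7.0)
        ws = segment_windows(x, 7)
        assert len(ws) == 1
        np.testing.assert_array_equal(ws.windows[0], x)

    def test_window_count(self):
        x = np.zeros((4, 63))
        assert len(segment_windows(x, 5)) == 4 * 59

    def test_labels_and_provenance_inherited(self):
        x = np.zeros((3, 5))
        ws = segment_windows(x, 4, labels=np.array([0, 1, 1]),
                             trajectory_ids=np.array([10, 20, 30]))
        np.testing.assert_array_equal(ws.labels, [0, 0, 1, 1, 1, 1])
        np.testing.assert_array_equal(ws.trajectory_ids, [10, 10, 20, 20, 30, 30])

    def test_oversized_window_error_names_both_values(self):
        with pytest.raises(ValueError, match="64.*63|63.*64"):
            segment_windows(np.zeros((1, 63)), 64)

    def test_single_sample_windows_allowed(self):
        ws = segment_windows(np.array([3.0, 1.0]), 1)
        assert len(ws) == 2 and ws.window_len == 1


class TestSplit:
    def test_stratified_trajectory_split(self, small_dataset, rng):
        tr, te = split_train_test(small_dataset, 0.5, rng)
        labels = small_dataset.labels
        assert len(tr) == len(te) == 8
        assert (labels[tr] == 0).sum() == 4 and (labels[te] == 0).sum() == 4

    def test_no_trajectory_on_both_sides(self, small_dataset, rng):
        tr, te = split_train_test(small_dataset, 0.5, rng)
        assert set(tr).isdisjoint(te)
        assert set(tr) | set(te) == set(range(len(small_dataset)))

    def test_split_determinism(self, small_dataset):
        r1 = np.random.default_rng(3)
        r2 = np.random.default_rng(3)
        a = split_train_test(small_dataset, 0.5, r1)
        b = split_train_test(small_dataset, 0.5, r2)
        np.testing.assert_array_equal(a[0], b[0])

    def test_invalid_fraction(self, small_dataset, rng):
        with pytest.raises(ValueError):
            split_train_test(small_dataset, 0.0, rng)


class TestZScore:
    def test_train_statistics_become_standard(self, rng):
        train = make_windows(rng.normal(5, 3, (50, 4)), np.zeros(50))
        test = make_windows(rng.normal(5, 3, (20, 4)), np.zeros(20))
        tr, _ = zscore_standardize(train, test)
        assert abs(tr.windows.mean()) <= 1e-10
        assert abs(tr.windows.std() - 1) <= 1e-10

    def test_test_set_uses_train_statistics(self):
        train = make_windows([[0.0, 0.0], [2.0, 2.0]], [0, 1])
        test = make_windows([[1.0, 1.0]], [0])
        _, te = zscore_standardize(train, test)
        # train mean 1, std 1 -> test window (1,1) maps to (0,0)
        np.testing.assert_allclose(te.windows, [[0.0, 0.0]])

    def test_constant_signal_passes_through_with_warning(self):
        train = make_windows(np.ones((5, 3)), np.zeros(5))
        test = make_windows(np.ones((2, 3)), np.zeros(2))
        with pytest.warns(UserWarning, match="constant"):
            tr, te = zscore_standardize(train, test)
        np.testing.assert_array_equal(tr.windows, np.ones((5, 3)))


class TestTrainAndEvaluate:
    def test_separable_classes_reach_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(-10, 0.1, (40, 3)), rng.normal(10, 0.1, (40, 3))])
        y = np.repeat([0, 1], 40)
        ws = make_windows(X, y)
        assert train_and_evaluate(ws, ws) == 1.0

    def test_shuffled_labels_score_at_chance(self, rng):
        X = rng.normal(0, 1, (3000, 3))
        y = rng.integers(0, 2, 3000)
        train = make_windows(X[:1000], y[:1000])
        test = make_windows(X[1000:], y[1000:])
        assert train_and_evaluate(train, test) == pytest.approx(0.5, abs=0.05)

    def test_single_class_training_rejected(self, rng):
        ws = make_windows(rng.normal(0, 1, (10, 2)), np.zeros(10))
        with pytest.raises(ValueError):
            train_and_evaluate(ws, ws)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(C=0.0)
        with pytest.raises(ValueError):
            ClassifierConfig(gamma=-1.0)


class TestEmpiricalKs:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(0, 1, 100)
        assert empirical_ks(x, x) == 0.0

    def test_disjoint_supports_give_one(self, rng):
        assert empirical_ks(rng.uniform(0, 1, 50), rng.uniform(5, 6, 70)) == 1.0

    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        a = np.array(data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60)))
        b = np.array(data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60)))
        assert empirical_ks(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            empirical_ks(np.array([]), np.array([1.0]))

    def test_converges_to_analytic_fabric_distance(self, rng):
        d1 = FabricPositionDistribution(float(1 - np.exp(-1)))
        d2 = FabricPositionDistribution(float(1 - np.exp(-4)))
        stat = empirical_ks(d1.rvs(100_000, rng), d2.rvs(100_000, rng))
        assert stat == pytest.approx(ks_distance_fabric(1.0, 2.0, 1.0), abs=0.01)


class TestPairedComparison:
    def test_equal_series_give_zero_median(self):
        a = np.linspace(0.6, 0.9, 8)
        res = paired_accuracy_comparison(a, a)
        assert res["median_pct"] == 0.0
        assert np.all(res["relative_diff_pct"] == 0.0)

    def test_uniform_multiplicative_gain(self):
        a = np.linspace(0.5, 0.9, 9)
        res = paired_accuracy_comparison(a, a * 1.021)
        assert res["median_pct"] == pytest.approx(2.1, abs=1e-9)
        assert res["n_b_greater"] == 9

    def test_all_positive_differences_significant_at_n13(self, rng):
        a = rng.uniform(0.6, 0.9, 13)
        b = a + rng.uniform(0.005, 0.03, 13)
        res = paired_accuracy_comparison(a, b)
        # exact signed-rank null: all-positive pattern has p = 2/2^13
        assert res["p_value"] == pytest.approx(2 / 2**13, rel=1e-9)
        assert res["p_value"] < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_accuracy_comparison([0.5] * 6, [0.5] * 7)


class TestActivityRecognitionModel:
    def test_window_conversion_and_results_shape(self, small_dataset):
        model = ActivityRecognition(small_dataset, "F3", 0.5)
        assert model.window_len == 5
        res = model.fit(n_trials=3, seed=0)
        assert res.n_trials == 3
        assert np.all((res.accuracies >= 0) & (res.accuracies <= 1))
        assert np.all((res.ks_stats >= 0) & (res.ks_stats <= 1))
        assert "accuracy" in res.summary()

    def test_fit_reproducible_under_seed(self, small_dataset):
        model = ActivityRecognition(small_dataset, "F1", 0.3)
        a = model.fit(n_trials=2, seed=5)
        b = model.fit(n_trials=2, seed=5)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_accuracy_invariant_to_common_affine_rescaling(self, small_dataset):
        scaled = TrajectoryDataset(
            [dataclasses.replace(
                t,
                rigid=None if t.rigid is None else 5.0 * t.rigid + 3.0,
                fabric={k: 5.0 * v + 3.0 for k, v in t.fabric.items()})
             for t in small_dataset.trajectories],
            small_dataset.spec)
        acc0 = ActivityRecognition(small_dataset, "F3", 0.5).fit(seed=1).accuracies
        acc1 = ActivityRecognition(scaled, "F3", 0.5).fit(seed=1).accuracies
        np.testing.assert_allclose(acc0, acc1)

    def test_analytic_ks_matches_distribution_layer(self, small_dataset):
        model = ActivityRecognition(small_dataset, "F3", 0.5)
        assert model.analytic_ks() == pytest.approx(ks_distance_fabric(1, 2, 1.0))
        rigid = ActivityRecognition(small_dataset, "R1", 0.5)
        assert rigid.analytic_ks() == 0.0
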