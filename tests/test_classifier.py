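"""Classifier: focal-loss formula, label smoothing, threshold calibration
against a brute-force oracle, training determinism and prediction contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smrtkin.classifier import (ClassifierConfig, calibrate_threshold,
                                feature_tensor, focal_loss, predict,
                                smooth_labels, train_classifier,
                                TrainedClassifier)
from smrtkin.evaluation import roc_auc
from smrtkin._nn import step_lr


class TestFocalLoss:
    def test_exact_value_at_half(self):
        assert focal_loss(0.5, gamma=2.0) == pytest.approx(0.25 * math.log(2),
                                                           abs=1e-9)

    def test_perfect_confidence_gives_zero(self):
        assert focal_loss(1.0, gamma=2.0) == pytest.approx(0.0, abs=1e-9)

    def test_gamma_zero_recovers_cross_entropy_on_grid(self):
        grid = np.linspace(0.01, 0.999, 100)
        for p in grid:
            assert focal_loss(p, gamma=0.0) == pytest.approx(-math.log(p),
                                                             rel=1e-12)

    def test_focal_never_exceeds_cross_entropy(self):
        grid = np.linspace(1e-4, 1 - 1e-9, 300)
        fl = np.array([focal_loss(p, gamma=2.0) for p in grid])
        ce = -np.log(grid)
        assert np.all(fl <= ce + 1e-15)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(1.2)
        with pytest.raises(ValueError):
            focal_loss(-0.1)


class TestSmoothLabels:
    def test_formula(self):
        t = smooth_labels([1, 0], 0.1)
        np.testing.assert_allclose(t[0], [0.05, 0.95])
        np.testing.assert_allclose(t[1], [0.95, 0.05])

    def test_zero_factor_is_identity(self):
        t = smooth_labels([0, 1], 0.0)
        np.testing.assert_array_equal(t, [[1, 0], [0, 1]])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50),
           st.floats(0.0, 0.49))
    def test_targets_sum_to_one(self, labels, factor):
        t = smooth_labels(labels, factor)
        np.testing.assert_allclose(t.sum(axis=1), 1.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            smooth_labels([0, 2], 0.1)
        with pytest.raises(ValueError):
            smooth_labels([0, 1], 0.5)


def _brute_force_best_f1(scores, labels):
    """Oracle: best F1 over a dense threshold sweep including all scores."""
    best = -1.0
    for thr in np.concatenate([[0.0, 1.0], np.unique(scores),
                               np.unique(scores) - 1e-9,
                               np.unique(scores) + 1e-9]):
        calls = scores >= thr
        tp = int(np.sum(calls & (labels == 1)))
        fp = int(np.sum(calls & (labels == 0)))
        fn = int(np.sum(~calls & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        best = max(best, f1)
    return best


class TestCalibrateThreshold:
    def test_perfect_separation_returns_midpoint(self):
        thr, f1 = calibrate_threshold(np.array([0.1, 0.4, 0.6, 0.9]),
                                      np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.5)
        assert f1 == pytest.approx(1.0)

    def test_all_positive_labels_push_threshold_to_floor(self):
        thr, f1 = calibrate_threshold(np.array([0.3, 0.6, 0.8]),
                                      np.array([1, 1, 1]))
        assert thr <= 0.3
        assert f1 == pytest.approx(1.0)

    def test_degenerate_scores_default_half_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            thr, _ = calibrate_threshold(np.full(6, 0.7),
                                         np.array([0, 1, 0, 1, 0, 1]))
        assert thr == 0.5

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.random(n).round(2)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max() or len(np.unique(scores)) == 1:
            return
        _, f1 = calibrate_threshold(scores, labels)
        assert f1 == pytest.approx(_brute_force_best_f1(scores, labels),
                                   abs=1e-12)


class TestTraining:
    def test_strong_signal_classifier_beats_chance_and_is_deterministic(
            self, tiny_sample_sets, tiny_regressor):
        train_set, test_set = tiny_sample_sets
        rng = np.random.default_rng(0)
        order = rng.permutation(len(train_set))
        n_tr = int(0.8 * len(train_set))
        tr = [train_set[i] for i in order[:n_tr]]
        va = [train_set[i] for i in order[n_tr:]]
        cfg = ClassifierConfig(epochs=400, step_size=100, gru_hidden=12, seed=4)
        clf_a = train_classifier(tr, va, 6, tiny_regressor, cfg)
        clf_b = train_classifier(tr, va, 6, tiny_regressor, cfg)
        assert clf_a.loss_trace == clf_b.loss_trace
        labels = np.array([1 if w.label == "methylated" else 0 for w in test_set])
        sa, calls_a = predict(clf_a, test_set, tiny_regressor)
        sb, _ = predict(clf_b, test_set, tiny_regressor)
        np.testing.assert_array_equal(sa, sb)
        assert roc_auc(sa, labels) > 0.9          # strong 6mA-like shift
        assert np.all((sa >= 0) & (sa <= 1))
        assert 0 < clf_a.threshold < 1
        # calls flip consistently with the threshold
        np.testing.assert_array_equal(calls_a, sa >= clf_a.threshold)

    def test_shuffled_labels_give_chance_auc(self, tiny_sample_sets, tiny_regressor):
        train_set, test_set = tiny_sample_sets
        rng = np.random.default_rng(1)
        shuffled = []
        labels = [w.label for w in train_set]
        perm = rng.permutation(len(labels))
        import copy
        for w, j in zip(train_set, perm):
            w2 = copy.copy(w)
            w2.label = labels[j]
            shuffled.append(w2)
        order = rng.permutation(len(shuffled))
        n_tr = int(0.8 * len(shuffled))
        tr = [shuffled[i] for i in order[:n_tr]]
        va = [shuffled[i] for i in order[n_tr:]]
        clf = train_classifier(tr, va, 7, None,
                               ClassifierConfig(epochs=10, gru_hidden=12, seed=5))
        test_labels = np.array([1 if w.label == "methylated" else 0
                                for w in test_set])
        scores, _ = predict(clf, test_set, None)
        assert 0.3 < roc_auc(scores, test_labels) < 0.7

    def test_single_class_input_rejected(self, tiny_sample_sets, tiny_regressor):
        train_set, _ = tiny_sample_sets
        pos_only = [w for w in train_set if w.label == "methylated"]
        assert len(pos_only) >= 25
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(pos_only[:20], pos_only[20:25], 6, tiny_regressor,
                             ClassifierConfig(epochs=1, gru_hidden=8, seed=6))

    def test_late_fusion_contract_parity(self, tiny_sample_sets, tiny_regressor):
        """Late fusion accepts the same inputs and yields scores in [0, 1]."""
        train_set, test_set = tiny_sample_sets
        rng = np.random.default_rng(2)
        order = rng.permutation(len(train_set))
        n_tr = int(0.8 * len(train_set))
        tr = [train_set[i] for i in order[:n_tr]]
        va = [train_set[i] for i in order[n_tr:]]
        cfg = ClassifierConfig(architecture="late_fusion", epochs=400,
                               step_size=100, gru_hidden=12, seed=7)
        clf = train_classifier(tr, va, 9, tiny_regressor, cfg)
        assert set(clf.net.branch_cols) == {"raw", "baseline", "seq"}
        scores, _ = predict(clf, test_set, tiny_regressor)
        assert np.all((scores >= 0) & (scores <= 1))
        labels = np.array([1 if w.label == "methylated" else 0 for w in test_set])
        assert roc_auc(scores, labels) > 0.8

    def test_checkpoint_round_trip(self, tiny_sample_sets, tiny_regressor, tmp_path):
        train_set, test_set = tiny_sample_sets
        tr, va = train_set[::2], train_set[1::2]
        clf = train_classifier(tr, va, 6, tiny_regressor,
                               ClassifierConfig(epochs=3, gru_hidden=8, seed=8))
        clf.save(tmp_path / "clf.npz")
        back = TrainedClassifier.load(tmp_path / "clf.npz")
        assert back.threshold == clf.threshold
        assert back.strategy == clf.strategy
        sa, _ = predict(clf, test_set, tiny_regressor)
        sb, _ = predict(back, test_set, tiny_regressor)
        np.testing.assert_array_equal(sa, sb)

    def test_frozen_baseline_unchanged_by_classifier_training(
            self, tiny_sample_sets, tiny_regressor):
        train_set, _ = tiny_sample_sets
        probe = ["ACGTACGTACGTACGTACGTA"]
        before = tiny_regressor.predict(probe).copy()
        tr, va = train_set[::2], train_set[1::2]
        train_classifier(tr, va, 6, tiny_regressor,
                         ClassifierConfig(epochs=2, gru_hidden=8, seed=9))
        np.testing.assert_array_equal(before, tiny_regressor.predict(probe))


def test_steplr_default_schedule_matches_closed_form():
    cfg = ClassifierConfig()
    for e in range(35):
        assert step_lr(cfg.lr, e, cfg.step_size, cfg.gamma_lr) == \
            pytest.approx(1e-3 * 0.5 ** (e // 10))


def test_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(label_smoothing=0.6)
    with pytest.raises(ValueError):
        ClassifierConfig(focal_gamma=-1)
    with pytest.raises(ValueError):
        ClassifierConfig(architecture="transformer")
    with pytest.raises(ValueError):
        ClassifierConfig(gamma_lr=0.0)
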