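"""Loss, AUROC/F1 metrics, bootstrap CIs and the training loop."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import squeezevit as sv
from squeezevit.errors import (
    ConfigurationError,
    ShapeError,
    UndefinedMetricError,
)
from oracles import auroc_pairs_oracle


class TestBceLoss:
    def test_logit_zero_label_one_is_ln2(self):
        assert sv.bce_loss(np.array([[0.0]]), np.array([[1.0]])) == \
            pytest.approx(math.log(2), rel=1e-12)

    def test_saturated_correct_logit_is_tiny(self):
        assert sv.bce_loss(np.array([[20.0]]), np.array([[1.0]])) <= 1e-8

    def test_hand_evaluated_2x2_case(self):
        z = np.array([[0.0, 1.0], [-1.0, 2.0]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        sig = 1 / (1 + np.exp(-z))
        want = -np.mean(y * np.log(sig) + (1 - y) * np.log(1 - sig))
        assert sv.bce_loss(z, y) == pytest.approx(want, rel=1e-12)

    def test_large_negative_logits_stay_finite(self):
        assert np.isfinite(sv.bce_loss(np.array([[-500.0]]),
                                       np.array([[1.0]])))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            sv.bce_loss(np.zeros((2, 3)), np.zeros((2, 2)))


class TestAuroc:
    def test_hand_case_three_of_four_pairs(self):
        assert sv.auroc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert sv.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert sv.auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sv.auroc([0.1, 0.9], [1, 1])

    def test_matches_exhaustive_pair_counting_100_draws(self):
        """Midrank Mann–Whitney equals brute-force pair counting exactly."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(4, 31)
            scores = np.round(rng.normal(size=n), 1)  # coarse: forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert sv.auroc(scores, labels) == \
                pytest.approx(auroc_pairs_oracle(scores, labels), abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        assert sv.auroc(scores, labels) == \
            pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            return
        base = sv.auroc(scores, labels)
        assert sv.auroc(np.exp(2 * scores), labels) == pytest.approx(base)
        assert sv.auroc(3 * scores - 7, labels) == pytest.approx(base)


class TestClasswise:
    def test_duplicate_classes_identical_aurocs(self, rng):
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        rep = sv.classwise_auroc(np.stack([s, s], 1), np.stack([y, y], 1))
        assert rep.per_class_auroc[0] == rep.per_class_auroc[1]

    def test_average_is_arithmetic_mean(self, rng):
        s = rng.random((60, 4))
        y = rng.integers(0, 2, (60, 4))
        rep = sv.classwise_auroc(s, y)
        assert rep.average_auroc == pytest.approx(
            np.nanmean(rep.per_class_auroc))

    def test_sample_permutation_invariance(self, rng):
        s = rng.random((40, 3))
        y = rng.integers(0, 2, (40, 3))
        perm = rng.permutation(40)
        a = sv.classwise_auroc(s, y).per_class_auroc
        b = sv.classwise_auroc(s[perm], y[perm]).per_class_auroc
        np.testing.assert_allclose(a, b)

    def test_degenerate_class_skipped_with_warning(self, rng):
        s = rng.random((20, 2))
        y = np.stack([rng.integers(0, 2, 20), np.ones(20, int)], 1)
        with pytest.warns(UserWarning, match="single label"):
            rep = sv.classwise_auroc(s, y)
        assert np.isnan(rep.per_class_auroc[1])

    def test_no_evaluable_class_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            sv.classwise_auroc(np.random.rand(5, 2), np.ones((5, 2), int))


class TestF1:
    def test_perfect_predictions(self):
        y = np.array([[1, 0], [0, 1]])
        assert sv.f1_average(y.astype(float), y) == 1.0

    def test_all_negative_predictions_on_positive_class(self):
        s = np.zeros((4, 1))
        y = np.ones((4, 1), int)
        assert sv.f1_average(s, y) == 0.0

    def test_hand_case_half(self):
        # TP=1, FP=1, FN=1 → F1 = 2/(2+1+1) = 0.5
        s = np.array([[0.9], [0.9], [0.1], [0.1]])
        y = np.array([[1], [0], [1], [0]])
        assert sv.f1_average(s, y) == 0.5

    def test_empty_class_contributes_zero(self):
        s = np.zeros((3, 2))
        s[:, 0] = [0.9, 0.9, 0.1]
        y = np.array([[1, 0], [1, 0], [0, 0]])
        assert sv.f1_average(s, y) == pytest.approx(0.5)  # (1.0 + 0.0)/2


class TestBootstrap:
    def test_perfect_separation_concentrates_at_one(self, rng):
        scores = np.concatenate([rng.random(300) + 2, rng.random(300)])
        labels = np.array([1] * 300 + [0] * 300)
        lo, hi = sv.bootstrap_ci(scores, labels, seed=3)
        assert lo >= 0.99 and hi <= 1.0

    def test_seed_determinism(self, rng):
        s = rng.random(80)
        y = rng.integers(0, 2, 80)
        assert sv.bootstrap_ci(s, y, seed=5) == sv.bootstrap_ci(s, y, seed=5)

    def test_interval_brackets_point_estimate(self, rng):
        s = rng.normal(size=150) + np.linspace(0, 1, 150)
        y = (np.linspace(0, 1, 150) > 0.5).astype(int)
        lo, hi = sv.bootstrap_ci(s, y, seed=1)
        assert lo <= sv.auroc(s, y) <= hi

    def test_small_b_warns(self, rng):
        s, y = rng.random(40), rng.integers(0, 2, 40)
        with pytest.warns(UserWarning, match="too few"):
            sv.bootstrap_ci(s, y, B=50, seed=0)


@pytest.fixture(scope="module")
def tiny():
    return sv.generate_synthetic(sv.SyntheticSpec(n_images=12, seed=31))


class TestTrainLoop:

    def test_refuses_empty_dataset(self, default_model):
        with pytest.raises(ConfigurationError, match="empty"):
            sv.train(default_model, np.zeros((0, 1, 224, 224)),
                     np.zeros((0, 14)))

    def test_refuses_constant_labels(self, default_model):
        with pytest.raises(ConfigurationError, match="constant"):
            sv.train(default_model, np.zeros((4, 1, 224, 224), np.float32),
                     np.ones((4, 14)))

    def test_same_seed_identical_loss_history(self, tiny):
        spec = sv.TrainSpec(batch_size=6, epochs=2, seed=3)
        losses = []
        for _ in range(2):
            model = sv.build_squeezevit(sv.NetworkConfig(seed=3))
            hist = sv.train(model, tiny.images, tiny.label_matrix, spec,
                            track_metrics=False)
            losses.append([h.loss for h in hist])
        assert losses[0] == losses[1]

    def test_history_one_record_per_epoch_with_metrics(self, tiny):
        model = sv.build_squeezevit(sv.NetworkConfig(seed=1))
        hist = sv.train(model, tiny.images, tiny.label_matrix,
                        sv.TrainSpec(batch_size=6, epochs=2, seed=0))
        assert len(hist) == 2
        assert all(h.auroc is not None and h.f1 is not None for h in hist)

    def test_binary_mode_consistency(self):
        """Collapsed-label AUROC equals AUROC on the binarized manifest."""
        # low prevalence so the draw contains genuinely normal images
        ds = sv.generate_synthetic(sv.SyntheticSpec(
            n_images=60, image_side=64, n_classes=6, prevalence=0.1, seed=2))
        bin_labels = sv.binarize_labels(ds.manifest).label_matrix().ravel()
        any_positive = (ds.label_matrix.sum(axis=1) > 0).astype(int)
        np.testing.assert_array_equal(bin_labels, any_positive)
        assert 0 < bin_labels.sum() < len(bin_labels)
        scores = sv.matched_filter_scores(ds.images, ds.templates)
        abnormality = scores.max(axis=1)
        assert sv.auroc(abnormality, bin_labels) == \
            sv.auroc(abnormality, any_positive)
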