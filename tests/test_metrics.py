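import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammogan import metrics as M
from mammogan.metrics import (
    ConfusionMatrix,
    EmbeddingStats,
    MetricError,
    RandomConvClassifier,
    RandomConvEmbedder,
    confusion_metrics,
    fid,
    frechet_distance,
    inception_score,
    mean_pairwise_ms_ssim,
    ms_ssim,
    psnr,
    roc_auc,
    ssim,
)


def _stats(mean, var):
    return EmbeddingStats(mean=np.atleast_1d(np.asarray(mean, float)),
                          cov=np.atleast_2d(np.asarray(var, float)), n=100)


class TestFrechet:
    def test_identical_stats_zero(self):
        s = _stats([0.0, 1.0], [[1.0, 0.2], [0.2, 2.0]])
        assert abs(frechet_distance(s, s)) < 1e-8

    @pytest.mark.parametrize(
        "m1,v1,m2,v2,expected",
        [
            (0.0, 1.0, 1.0, 1.0, 1.0),   # mean shift only
            (0.0, 1.0, 0.0, 4.0, 1.0),   # sigma 1 vs 2
            (2.0, 9.0, -1.0, 1.0, 13.0),  # (3)^2 + (3-1)^2
        ],
    )
    def test_univariate_closed_form(self, m1, v1, m2, v2, expected):
        d = frechet_distance(_stats(m1, v1), _stats(m2, v2))
        assert abs(d - expected) < 1e-8

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = EmbeddingStats.from_features(rng.standard_normal((40, 6)))
        b = EmbeddingStats.from_features(rng.standard_normal((40, 6)) * 2 + 1)
        assert frechet_distance(a, b) == frechet_distance(b, a)

    def test_dimension_mismatch(self):
        with pytest.raises(MetricError):
            frechet_distance(_stats([0.0], 1.0), _stats([0.0, 0.0], np.eye(2)))


class TestFid:
    def test_set_against_itself_is_tiny(self):
        rng = np.random.default_rng(1)
        imgs = rng.integers(0, 256, size=(12, 32, 32), dtype=np.uint8)
        assert fid(imgs, imgs) < 1e-3

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 256, size=(10, 32, 32), dtype=np.uint8)
        b = rng.integers(0, 256, size=(10, 32, 32), dtype=np.uint8)
        assert fid(a, b) == fid(b, a)

    def test_agrees_with_two_step_computation(self):
        """Decomposition oracle: embed, fit stats, take the Fréchet distance
        by hand; must equal the one-call fid on 10+10 phantoms."""
        from mammogan.phantom import generate_dataset
        from mammogan.preprocess import PreprocessConfig, preprocess_phantom

        cfg = PreprocessConfig(target_size=32)
        recs = generate_dataset(10, 10, seed=31)
        imgs = np.stack([preprocess_phantom(r, cfg).pixels for r in recs])
        real, fake = imgs[:10], imgs[10:]
        emb = RandomConvEmbedder(seed=5)
        expected = frechet_distance(
            EmbeddingStats.from_features(emb(real)),
            EmbeddingStats.from_features(emb(fake)),
        )
        assert fid(real, fake, embedder=emb) == expected

    def test_too_few_samples_rejected(self):
        with pytest.raises(MetricError):
            fid(np.zeros((1, 16, 16)), np.zeros((5, 16, 16)))


class TestInceptionScore:
    def test_constant_classifier_gives_one(self):
        clf = lambda imgs: np.full((len(imgs), 4), 0.25)
        mean, std = inception_score(np.zeros((8, 16, 16)), classifier=clf, n_splits=1)
        assert abs(mean - 1.0) < 1e-12
        assert std == 0.0

    def test_confident_uniform_classifier_gives_k(self):
        k = 5
        clf = lambda imgs: np.eye(k)[np.arange(len(imgs)) % k]
        mean, _ = inception_score(np.zeros((10, 16, 16)), classifier=clf, n_splits=1)
        assert abs(mean - k) < 1e-9

    def test_score_bounded_by_class_count(self):
        rng = np.random.default_rng(3)
        imgs = rng.integers(0, 256, size=(16, 32, 32), dtype=np.uint8)
        clf = RandomConvClassifier(seed=1, n_classes=10)
        mean, _ = inception_score(imgs, classifier=clf, n_splits=2)
        assert 1.0 <= mean <= 10.0

    def test_non_simplex_output_rejected(self):
        clf = lambda imgs: np.full((len(imgs), 3), 0.5)
        with pytest.raises(MetricError):
            inception_score(np.zeros((4, 16, 16)), classifier=clf)


class TestSsim:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, size=(200, 200)).astype(np.uint8)
        assert ms_ssim(img, img) == pytest.approx(1.0, abs=1e-9)
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 256, size=(180, 180)).astype(np.uint8)
        b = np.clip(a.astype(int) + rng.integers(-30, 30, a.shape), 0, 255).astype(np.uint8)
        assert ms_ssim(a, b) == pytest.approx(ms_ssim(b, a), rel=1e-12)

    def test_constant_images_match_closed_form(self):
        """SSIM of two constant images has the closed form
        (2 mu_a mu_b + C1) / (mu_a^2 + mu_b^2 + C1)."""
        a = np.full((11, 11), 100, dtype=np.uint8)
        b = np.full((11, 11), 110, dtype=np.uint8)
        c1 = (0.01 * 255) ** 2
        expected = (2 * 100 * 110 + c1) / (100**2 + 110**2 + c1)
        assert ssim(a, b) == pytest.approx(expected, rel=1e-10)

    def test_single_scale_matches_skimage(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(6)
        a = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        b = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False, data_range=255
        )
        assert ssim(a, b) == pytest.approx(ref, abs=1e-7)

    def test_too_small_image_rejected(self):
        with pytest.raises(MetricError):
            ms_ssim(np.zeros((32, 32)), np.zeros((32, 32)), scales=5)

    def test_mean_pairwise_identical_set(self):
        imgs = [np.full((176, 176), 80, dtype=np.uint8)] * 4
        assert mean_pairwise_ms_ssim(imgs, n_pairs=3, seed=0) == pytest.approx(1.0)

    def test_mean_pairwise_seeded_and_bounded(self):
        rng = np.random.default_rng(7)
        imgs = [rng.integers(0, 256, size=(48, 48)).astype(np.uint8) for _ in range(6)]
        v1 = mean_pairwise_ms_ssim(imgs, n_pairs=5, seed=9, scales=3)
        v2 = mean_pairwise_ms_ssim(imgs, n_pairs=5, seed=9, scales=3)
        assert v1 == v2
        with pytest.raises(MetricError):
            mean_pairwise_ms_ssim(imgs, n_pairs=100, seed=0, scales=3)


class TestPsnr:
    def test_identical_images_infinite(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        assert psnr(img, img) == math.inf

    def test_unit_mse_closed_form(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.ones((10, 10), dtype=np.uint8)
        assert psnr(a, b) == pytest.approx(10 * math.log10(255**2), abs=1e-9)
        assert psnr(a, b) == pytest.approx(48.1308, abs=1e-3)

    def test_full_scale_error_is_zero_db(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.full((4, 4), 255, dtype=np.uint8)
        assert psnr(a, b) == pytest.approx(0.0, abs=1e-12)


class TestConfusionMetrics:
    def test_fifty_cancer_arm_sensitivity(self):
        m = confusion_metrics(ConfusionMatrix(tp=39, tn=26, fp=24, fn=11))
        assert m["sensitivity"] == pytest.approx(78.0)
        assert m["specificity"] == pytest.approx(52.0)
        assert m["accuracy"] == pytest.approx(65.0)

    def test_all_ones_gives_fifty_percent(self):
        m = confusion_metrics(ConfusionMatrix(1, 1, 1, 1))
        assert all(v == pytest.approx(50.0) for v in m.values())

    def test_perfect_ppv_when_no_false_positives(self):
        m = confusion_metrics(ConfusionMatrix(tp=5, tn=3, fp=0, fn=2))
        assert m["ppv"] == pytest.approx(100.0)

    def test_zero_denominator_flagged_not_zero(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m["ppv"])  # no predicted positives
        assert math.isnan(m["sensitivity"])  # no true positives
        assert m["specificity"] == pytest.approx(100.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_accuracy_is_prevalence_weighted_combination(self, tp, tn, fp, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        cm = ConfusionMatrix(tp, tn, fp, fn)
        m = confusion_metrics(cm)
        prev = (tp + fn) / cm.total
        combo = prev * m["sensitivity"] + (1 - prev) * m["specificity"]
        assert m["accuracy"] == pytest.approx(combo, abs=1e-9)


def _auc_bruteforce(scores, labels01):
    """Mann-Whitney pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels01) if y == 1]
    neg = [s for s, y in zip(scores, labels01) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([5, 6, 7, 1, 2, 3], ["cancer"] * 3 + ["normal"] * 3)
        assert auc == pytest.approx(1.0)
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_all_tied_scores_give_half(self):
        auc, _ = roc_auc([2.0] * 8, ["cancer"] * 4 + ["normal"] * 4)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.standard_normal(n), 1)  # rounding forces ties
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(_auc_bruteforce(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([1, 2], ["cancer", "cancer"])
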