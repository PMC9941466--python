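"""Evaluation statistics for generative quality and classification.

Generative side: Fréchet distance between Gaussian embedding statistics (FID
when the embeddings come from an image feature network), inception score,
multiscale structural similarity (MS-SSIM) and PSNR.  The feature network and
the classifier are pluggable: the packaged defaults are small fixed-seed random
convolutional networks, so every statistic is computable offline and
deterministically; an ImageNet-pretrained network can be plugged in by users
who want values comparable to the published literature.

Classification side: exact rational confusion-matrix metrics (accuracy,
sensitivity, specificity, PPV, NPV, reported as percentages) and ROC/AUC with
Mann-Whitney tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import math

import numpy as np
from scipy import signal

POSITIVE_LABEL = "cancer"
NEGATIVE_LABEL = "normal"


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fréchet distance / FID
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingStats:
    """Gaussian summary (mean, covariance) of a set of feature vectors."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    @classmethod
    def from_features(cls, feats: np.ndarray) -> "EmbeddingStats":
        feats = np.asarray(feats, dtype=np.float64)
        if feats.ndim != 2 or feats.shape[0] < 2:
            raise MetricError("need a (n >= 2, d) feature matrix")
        return cls(mean=feats.mean(axis=0), cov=np.cov(feats, rowvar=False), n=feats.shape[0])


def _sqrtm_psd(m: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def _tr_sqrt_product(sa: np.ndarray, sb: np.ndarray) -> float:
    a = _sqrtm_psd(sa)
    vals = np.linalg.eigvalsh((a @ sb @ a + (a @ sb @ a).T) / 2.0)
    return float(np.sqrt(np.clip(vals, 0.0, None)).sum())


def frechet_distance(a: EmbeddingStats, b: EmbeddingStats, eps: float = 1e-6) -> float:
    """Fréchet (2-Wasserstein²) distance between two Gaussians:
    ||μa − μb||² + Tr(Σa + Σb − 2(ΣaΣb)^1/2).

    Near-singular covariances are regularised with εI; the matrix square root
    is taken by eigendecomposition of the symmetrised product with small
    negative eigenvalues clamped to zero.  The trace term is averaged over both
    operand orders so the result is exactly symmetric.
    """
    if a.mean.shape != b.mean.shape:
        raise MetricError("embedding dimension mismatch")
    sa = np.atleast_2d(np.asarray(a.cov, dtype=np.float64))
    sb = np.atleast_2d(np.asarray(b.cov, dtype=np.float64))
    if min(np.linalg.eigvalsh(sa).min(), np.linalg.eigvalsh(sb).min()) < eps:
        sa = sa + eps * np.eye(sa.shape[0])
        sb = sb + eps * np.eye(sb.shape[0])
    diff = np.asarray(a.mean, dtype=np.float64) - np.asarray(b.mean, dtype=np.float64)
    tr_sqrt = 0.5 * (_tr_sqrt_product(sa, sb) + _tr_sqrt_product(sb, sa))
    # fsum gives a correctly-rounded total, so the distance is exactly
    # symmetric in its arguments
    return math.fsum([float(diff @ diff), float(np.trace(sa)), float(np.trace(sb)), -2.0 * tr_sqrt])


class RandomConvEmbedder:
    """Fixed-seed random convolutional feature network.

    Strided 3x3 convolutions with leaky-ReLU halve the resolution per layer
    down to <= 4 px, followed by global average pooling.  Purely a feature
    embedding for distributional comparison — untrained by design, which keeps
    FID computable offline; absolute values are not comparable to
    pretrained-Inception FIDs.
    """

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = (8, 16, 32, 64)):
        self.seed = seed
        self.channels = tuple(channels)
        self._weights: dict[tuple[int, int], list[np.ndarray]] = {}

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    def _layers(self, in_ch: int, side: int) -> list[np.ndarray]:
        key = (in_ch, side)
        if key not in self._weights:
            rng = np.random.default_rng(np.random.SeedSequence((self.seed, in_ch, side)))
            layers = []
            c_in, s = in_ch, side
            for c_out in self.channels:
                if s <= 4:
                    break
                w = rng.standard_normal((c_out, c_in, 3, 3)) * math.sqrt(2.0 / (c_in * 9))
                layers.append(w.astype(np.float32))
                c_in, s = c_out, (s + 1) // 2
            self._weights[key] = layers
        return self._weights[key]

    def __call__(self, images: np.ndarray) -> np.ndarray:
        from ._autodiff import _im2col_np

        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        x = x / 127.5 - 1.0
        for w in self._layers(x.shape[1], x.shape[2]):
            cout = w.shape[0]
            k = w.shape[2]
            b, _, h, _ = x.shape
            ho = (h + 2 - k) // 2 + 1
            cols = _im2col_np(x, k, stride=2, pad=1)
            x = (cols @ w.reshape(cout, -1).T).transpose(0, 2, 1).reshape(b, cout, ho, ho)
            x = np.where(x > 0, x, 0.2 * x)
        feats = x.mean(axis=(2, 3))
        if feats.shape[1] < self.feature_dim:  # pad for tiny inputs
            feats = np.pad(feats, ((0, 0), (0, self.feature_dim - feats.shape[1])))
        return feats.astype(np.float64)


def fid(real_images, fake_images, embedder=None, eps: float = 1e-6) -> float:
    """Fréchet distance between embedding statistics of two image sets."""
    if embedder is None:
        embedder = RandomConvEmbedder()
    real = np.asarray(real_images)
    fake = np.asarray(fake_images)
    if len(real) < 2 or len(fake) < 2:
        raise MetricError("need at least 2 images per side for FID")
    sa = EmbeddingStats.from_features(embedder(real))
    sb = EmbeddingStats.from_features(embedder(fake))
    return frechet_distance(sa, sb, eps=eps)


# ---------------------------------------------------------------------------
# Inception score
# ---------------------------------------------------------------------------

class RandomConvClassifier:
    """Fixed-seed random conv features followed by a random softmax head."""

    def __init__(self, seed: int = 0, n_classes: int = 10):
        self.n_classes = n_classes
        self._embed = RandomConvEmbedder(seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence((seed, n_classes, 7)))
        self._head = rng.standard_normal((self._embed.feature_dim, n_classes))

    def __call__(self, images: np.ndarray) -> np.ndarray:
        logits = self._embed(images) @ self._head
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


def inception_score(images, classifier=None, n_splits: int = 1) -> tuple[float, float]:
    """exp(E_x KL(p(y|x) || p(y))) per split; returns (mean, std) over splits."""
    if classifier is None:
        classifier = RandomConvClassifier()
    images = np.asarray(images)
    n = len(images)
    if n_splits < 1 or n < n_splits:
        raise MetricError("need at least one image per split")
    probs = np.asarray(classifier(images), dtype=np.float64)
    if probs.ndim != 2 or (probs < -1e-9).any() or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise MetricError("classifier must return rows on the probability simplex")
    scores = []
    for chunk in np.array_split(probs, n_splits):
        marginal = chunk.mean(axis=0, keepdims=True)
        kl = np.where(chunk > 0, chunk * (np.log(chunk + 1e-300) - np.log(marginal + 1e-300)), 0.0)
        scores.append(math.exp(kl.sum(axis=1).mean()))
    return float(np.mean(scores)), float(np.std(scores))


# ---------------------------------------------------------------------------
# (MS-)SSIM and PSNR
# ---------------------------------------------------------------------------

_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_maps(a: np.ndarray, b: np.ndarray, data_range: float, k1=0.01, k2=0.03):
    """Luminance and contrast-structure maps over valid 11x11 windows."""
    kern = _gaussian_kernel()
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a = signal.convolve2d(a, kern, mode="valid")
    mu_b = signal.convolve2d(b, kern, mode="valid")
    var_a = signal.convolve2d(a * a, kern, mode="valid") - mu_a**2
    var_b = signal.convolve2d(b * b, kern, mode="valid") - mu_b**2
    cov = signal.convolve2d(a * b, kern, mode="valid") - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def ssim(a, b, data_range: float = 255.0) -> float:
    """Single-scale SSIM (11-tap Gaussian window, sigma 1.5, K1/K2 = .01/.03)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError("image shape mismatch")
    if min(a.shape) < 11:
        raise MetricError("images must be at least 11 px per side")
    lum, cs = _ssim_maps(a, b, data_range)
    return float((lum * cs).mean())


def ms_ssim(a, b, data_range: float = 255.0, scales: int = 5) -> float:
    """Multiscale SSIM with the standard 5-scale exponents.

    Contrast-structure terms at the finer scales, luminance times
    contrast-structure at the coarsest, combined as a weighted geometric mean.
    Scale transitions are 2x2 average pooling.  With fewer than 5 scales (for
    small images) the leading exponents are renormalised to sum to one.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError("image shape mismatch")
    if not 1 <= scales <= 5:
        raise MetricError("scales must be in 1..5")
    if min(a.shape) < 11 * 2 ** (scales - 1):
        raise MetricError(
            f"images of shape {a.shape} too small for {scales} scales "
            f"(need >= {11 * 2 ** (scales - 1)} px per side)"
        )
    weights = np.asarray(_MSSSIM_WEIGHTS[:scales])
    weights = weights / weights.sum()
    value = 1.0
    for level in range(scales):
        lum, cs = _ssim_maps(a, b, data_range)
        term = (lum * cs).mean() if level == scales - 1 else cs.mean()
        # structurally unrelated images can give a (slightly) negative mean
        # contrast-structure; clamp before the fractional exponent
        value *= max(float(term), 0.0) ** weights[level]
        if level < scales - 1:
            h, w = (a.shape[0] // 2) * 2, (a.shape[1] // 2) * 2
            a = a[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            b = b[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    return value


def mean_pairwise_ms_ssim(images, n_pairs: int = 50, seed: int = 0, **kwargs) -> float:
    """Mean MS-SSIM over ``n_pairs`` distinct random image pairs (diversity
    probe: lower values mean more diverse generations)."""
    images = list(images)
    n = len(images)
    if n < 2:
        raise MetricError("need at least 2 images")
    total = n * (n - 1) // 2
    if n_pairs > total:
        raise MetricError(f"n_pairs={n_pairs} exceeds the {total} distinct pairs available")
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, k=1)
    chosen = rng.choice(total, size=n_pairs, replace=False)
    vals = [ms_ssim(images[ii[c]], images[jj[c]], **kwargs) for c in np.sort(chosen)]
    return float(np.mean(vals))


def psnr(a, b, max_val: float = 255.0) -> float:
    """10·log10(max_val² / MSE); identical images give +inf."""
    if max_val <= 0:
        raise MetricError("max_val must be positive")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError("image shape mismatch")
    mse = float(((a - b) ** 2).mean())
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val**2 / mse)


# ---------------------------------------------------------------------------
# Confusion metrics and ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricError("confusion counts must be non-negative")
        if self.total == 0:
            raise MetricError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV as exact-rational
    percentages.  A metric with a zero denominator is reported as NaN (an
    explicit undefined flag), never silently as 0."""

    def pct(num: int, den: int) -> float:
        if den == 0:
            return math.nan
        return float(Fraction(num, den) * 100)

    return {
        "accuracy": pct(cm.tp + cm.tn, cm.total),
        "sensitivity": pct(cm.tp, cm.tp + cm.fn),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
        "ppv": pct(cm.tp, cm.tp + cm.fp),
        "npv": pct(cm.tn, cm.tn + cm.fn),
    }


def _binary_labels(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in (POSITIVE_LABEL, NEGATIVE_LABEL):
                raise MetricError(f"unknown label {lab!r}")
            out.append(1 if lab == POSITIVE_LABEL else 0)
        else:
            out.append(int(bool(lab)))
    return np.asarray(out)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC (trapezoidal over all distinct-score thresholds; ties get half
    credit, i.e. the Mann-Whitney U convention) plus the ROC curve points as an
    array of (fpr, tpr) rows."""
    from sklearn import metrics as skm

    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise MetricError("both classes must be present for ROC analysis")
    fpr, tpr, _ = skm.roc_curve(y, s)
    auc = float(skm.auc(fpr, tpr))
    return auc, np.column_stack([fpr, tpr])
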