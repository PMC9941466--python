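"""Latent-space projection: map a test image back into the generator's W space.

For each seed, optimisation starts at the mapping-network image of that seed's
latent z and runs Adam on a single w vector, minimising a perceptual distance
between the synthesised image and the target.  The best-loss iterate (not the
last) is returned, so the reported loss is monotone in the step budget.  With
several seeds the per-seed reconstructions are averaged pixelwise into one
mean image — the reconstruction the anomaly stage compares against.

The default perceptual distance is a small fixed-seed random convolutional
pyramid plus a pixel-MSE term: deterministic, offline, and sensitive to both
coarse structure and local texture.  Any network exposing the same interface
(e.g. a pretrained LPIPS-style feature stack) can be plugged in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .preprocess import NormalizedImage, round_half_up
from .stylegen import GeneratorModel, LatentW, map_latent, sample_z, to_uint8


class ProjectionError(ValueError):
    pass


class PerceptualExtractor:
    """Fixed-seed random conv pyramid defining a perceptual distance.

    distance(a, b) = pixel_weight * MSE(a, b)
                   + sum_l layer_weights[l] * MSE(f_l(a), f_l(b))

    where f_l are leaky-ReLU feature maps of stride-2 3x3 convolutions whose
    weights are drawn once from ``seed``.  The distance is symmetric,
    non-negative and zero iff a == b (whenever pixel_weight > 0).
    """

    def __init__(
        self,
        seed: int = 0,
        channels: tuple[int, ...] = (8, 16, 32),
        layer_weights: tuple[float, ...] | None = None,
        pixel_weight: float = 1.0,
    ):
        self.seed = seed
        self.channels = tuple(channels)
        self.layer_weights = tuple(layer_weights) if layer_weights is not None else (1.0,) * len(self.channels)
        if len(self.layer_weights) != len(self.channels):
            raise ProjectionError("layer_weights must match the number of feature layers")
        self.pixel_weight = float(pixel_weight)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFE)))
        self._weights = []
        c_in = 1
        for c_out in self.channels:
            w = rng.standard_normal((c_out, c_in, 3, 3)) * math.sqrt(2.0 / (c_in * 9))
            self._weights.append(Tensor(w.astype(np.float32)))
            c_in = c_out

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        for w in self._weights:
            if x.shape[2] < 2:
                break
            x = ad.leaky_relu(ad.conv2d(x, w, stride=2, pad=1), 0.2)
            feats.append(x)
        return feats

    def loss_t(self, a: Tensor, b: Tensor) -> Tensor:
        """Differentiable distance between (B,1,H,W) tensors."""
        diff = ad.add(a, ad.mul(b, -1.0))
        total = ad.mul(ad.tmean(ad.mul(diff, diff)), self.pixel_weight)
        if any(w != 0 for w in self.layer_weights):
            fa, fb = self.features(a), self.features(b)
            for wl, xa, xb in zip(self.layer_weights, fa, fb):
                if wl == 0:
                    continue
                d = ad.add(xa, ad.mul(xb, -1.0))
                total = ad.add(total, ad.mul(ad.tmean(ad.mul(d, d)), wl))
        return total


def _as_batch_tensor(image) -> Tensor:
    arr = np.asarray(image.pixels if isinstance(image, NormalizedImage) else image)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 127.5 - 1.0
    arr = arr.astype(np.float32)
    if arr.ndim != 2:
        raise ProjectionError(f"expected a 2-D image, got shape {arr.shape}")
    return Tensor(arr[None, None])


def perceptual_loss(a, b, extractor: PerceptualExtractor | None = None) -> float:
    """Perceptual distance between two equal-shape images (as given, no
    rescaling: with a pixel-only extractor this is exactly the pixel MSE)."""
    a = np.asarray(a, dtype=np.float32)
    b = np.asarray(b, dtype=np.float32)
    if a.shape != b.shape:
        raise ProjectionError(f"shape mismatch: {a.shape} vs {b.shape}")
    extractor = extractor or PerceptualExtractor()
    with ad.no_grad():
        val = extractor.loss_t(Tensor(a[None, None]), Tensor(b[None, None]))
    return float(val.data)


@dataclass
class ProjectionResult:
    """One seed's projection: final latent, reconstruction and loss curve."""

    seed: int
    w_final: LatentW
    image: np.ndarray  # 8-bit reconstruction
    loss_trajectory: list[float]
    final_loss: float


@dataclass
class MultiSeedProjection:
    per_seed: list[ProjectionResult]
    mean_image: np.ndarray

    @property
    def n_seeds(self) -> int:
        return len(self.per_seed)


def project(
    target,
    model: GeneratorModel,
    seed: int = 0,
    steps: int = 300,
    extractor: PerceptualExtractor | None = None,
    learning_rate: float = 0.05,
) -> ProjectionResult:
    """Project ``target`` onto the generator manifold from one seed.

    Deterministic given (target, model parameters, seed, steps, extractor):
    the synthesis noise is frozen at ``noise_seed = seed`` for the whole
    optimisation, and the best-loss iterate is returned.
    """
    if steps < 1:
        raise ProjectionError("steps must be >= 1")
    extractor = extractor or PerceptualExtractor()
    target_t = _as_batch_tensor(target)
    res = model.config.resolution
    if target_t.shape[2:] != (res, res):
        raise ProjectionError(
            f"target resolution {target_t.shape[2:]} does not match model resolution {res}"
        )
    w0 = map_latent(sample_z(model.config, seed), model)
    w = Tensor(w0.vector[None].copy(), requires_grad=True)
    opt = ad.Adam([w], lr=learning_rate, betas=(0.9, 0.999))
    trajectory: list[float] = []
    best_loss, best_w = math.inf, w.data.copy()
    for _ in range(steps):
        img = model.forward_synthesis(w, noise_seed=seed)
        loss = extractor.loss_t(img, target_t)
        val = float(loss.data)
        trajectory.append(val)
        if val < best_loss:
            best_loss, best_w = val, w.data.copy()
        opt.zero_grad()
        loss.backward()
        opt.step()
    with ad.no_grad():
        final_img = model.forward_synthesis(Tensor(best_w), noise_seed=seed)
    return ProjectionResult(
        seed=seed,
        w_final=LatentW(vector=best_w[0].copy()),
        image=to_uint8(final_img.data[0, 0]),
        loss_trajectory=trajectory,
        final_loss=best_loss,
    )


def multi_seed_project(
    target,
    model: GeneratorModel,
    seeds,
    steps: int = 300,
    extractor: PerceptualExtractor | None = None,
    learning_rate: float = 0.05,
) -> MultiSeedProjection:
    """Independent projections from each seed plus their pixelwise mean image
    (half-up rounded); the mean does not depend on seed order."""
    seeds = list(seeds)
    if not seeds:
        raise ProjectionError("need at least one seed")
    if len(set(seeds)) != len(seeds):
        raise ProjectionError("seeds must be distinct")
    results = [
        project(target, model, seed=s, steps=steps, extractor=extractor, learning_rate=learning_rate)
        for s in seeds
    ]
    stack = np.stack([r.image.astype(np.int64) for r in sorted(results, key=lambda r: r.seed)])
    mean_image = np.clip(round_half_up(stack.sum(axis=0) / len(stack)), 0, 255).astype(np.uint8)
    return MultiSeedProjection(per_seed=results, mean_image=mean_image)
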