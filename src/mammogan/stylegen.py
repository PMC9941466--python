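"""A reduced, configurable style-based generative adversarial network.

The architecture keeps the three mechanisms that define the second-generation
style architecture — a deep MLP mapping network from the latent space Z to an
intermediate space W, weight-demodulated (style-modulated) convolutions in the
synthesis network, and per-pixel Gaussian noise injection after each
convolution — while scaling channel widths and resolution down to sizes
trainable on a single CPU.  Progressive growth is not used (a skip-connection
generator and a residual discriminator stand in its place, as in the reference
design).

Training is the non-saturating logistic GAN objective with R1 gradient
regularisation on real batches, optimised with Adam.  Snapshots are taken at a
fixed interval and scored with the Fréchet distance against a held-out real
batch; :func:`select_best_snapshot` returns the minimum-FID snapshot, which
guards against late-training mode collapse.

Everything is seeded: parameter initialisation, data order, latent draws and
noise injection, so a run is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .metrics import RandomConvEmbedder, fid as compute_fid
from .preprocess import NormalizedImage, round_half_up


class StyleGanError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration and latent types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    z_dim: int = 64
    w_dim: int = 64
    mapping_layers: int = 8
    base_channels: int = 32
    max_channels: int = 64
    resolution: int = 32
    noise_injection: bool = True
    learning_rate: float = 0.001
    batch_size: int = 8
    r1_gamma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.resolution not in (16, 32, 64, 128, 256, 512):
            raise StyleGanError("resolution must be a power of two in 16..512")
        if self.learning_rate <= 0:
            raise StyleGanError("learning_rate must be positive")
        if self.mapping_layers < 1:
            raise StyleGanError("mapping_layers must be >= 1")

    def channels(self, res: int) -> int:
        """Channel width at a synthesis/discriminator resolution: halves per
        doubling from ``base_channels`` at 4x4, clamped to [8, max_channels]."""
        c = self.base_channels * 4 // res
        return int(min(self.max_channels, max(8, c)))

    def resolutions(self) -> list[int]:
        out, r = [], 4
        while r <= self.resolution:
            out.append(r)
            r *= 2
        return out


@dataclass(frozen=True)
class LatentZ:
    """A standard-normal latent vector with its generating seed."""

    vector: np.ndarray
    seed: int


@dataclass(frozen=True)
class LatentW:
    """An intermediate-space latent (image of a LatentZ under the mapping net)."""

    vector: np.ndarray


def sample_z(config: GeneratorConfig, seed: int) -> LatentZ:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5A)))
    return LatentZ(vector=rng.standard_normal(config.z_dim).astype(np.float32), seed=seed)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _init_w(rng, shape, fan_in) -> np.ndarray:
    return (rng.standard_normal(shape) / math.sqrt(fan_in)).astype(np.float32)


class ModulatedConv2d:
    """Style-modulated convolution with optional weight demodulation.

    Per sample, weights are scaled by a style vector over input channels; with
    demodulation each output channel is renormalised to unit scale, which makes
    the layer's output statistics invariant to a positive rescaling of the
    style vector (the property that replaced adaptive instance normalisation).
    """

    def __init__(self, weight: Tensor, demodulate: bool = True, eps: float = 1e-8):
        self.weight = weight  # (Cout, Cin, k, k)
        self.demodulate = demodulate
        self.eps = eps

    def __call__(self, x: Tensor, style: Tensor) -> Tensor:
        b = x.shape[0]
        cout, cin, k, _ = self.weight.shape
        w = ad.reshape(self.weight, (1, cout, cin, k, k))
        s = ad.reshape(style, (b, 1, cin, 1, 1))
        w = ad.mul(w, s)  # (B, Cout, Cin, k, k)
        if self.demodulate:
            denom = ad.rsqrt(ad.tsum(ad.mul(w, w), axis=(2, 3, 4), keepdims=True) + self.eps)
            w = ad.mul(w, denom)
        return ad.batched_conv2d(x, w, stride=1, pad=k // 2)


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

class GeneratorModel:
    """Mapping network + skip-connection synthesis network parameters."""

    def __init__(self, config: GeneratorConfig, params: dict[str, Tensor]):
        self.config = config
        self.params = params

    # -- construction ---------------------------------------------------------
    @classmethod
    def initialize(cls, config: GeneratorConfig, seed: int | None = None) -> "GeneratorModel":
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed if seed is None else seed, 0x6E))
        )
        p: dict[str, np.ndarray] = {}
        dim_in = config.z_dim
        for i in range(config.mapping_layers):
            p[f"map.{i}.w"] = _init_w(rng, (dim_in, config.w_dim), dim_in)
            p[f"map.{i}.b"] = np.zeros(config.w_dim, dtype=np.float32)
            dim_in = config.w_dim
        c4 = config.channels(4)
        p["const"] = rng.standard_normal((1, c4, 4, 4)).astype(np.float32)
        for r in config.resolutions():
            cin = config.channels(max(r // 2, 4) if r > 4 else 4)
            cout = config.channels(r)
            p[f"g{r}.affine.w"] = _init_w(rng, (config.w_dim, cin), config.w_dim)
            p[f"g{r}.affine.b"] = np.ones(cin, dtype=np.float32)
            p[f"g{r}.conv.w"] = _init_w(rng, (cout, cin, 3, 3), cin * 9)
            p[f"g{r}.conv.b"] = np.zeros((1, cout, 1, 1), dtype=np.float32)
            p[f"g{r}.noise"] = np.full((), 0.1, dtype=np.float32)
            p[f"g{r}.rgb.affine.w"] = _init_w(rng, (config.w_dim, cout), config.w_dim)
            p[f"g{r}.rgb.affine.b"] = np.ones(cout, dtype=np.float32)
            p[f"g{r}.rgb.w"] = _init_w(rng, (1, cout, 1, 1), cout)
            p[f"g{r}.rgb.b"] = np.zeros((1, 1, 1, 1), dtype=np.float32)
        params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}
        return cls(config, params)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.astype(np.float32).copy()

    def copy(self) -> "GeneratorModel":
        m = GeneratorModel(self.config, {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()})
        return m

    @property
    def n_mapping_stages(self) -> int:
        return sum(1 for k in self.params if k.startswith("map.") and k.endswith(".w"))

    # -- forward passes (Tensor-level, differentiable) ------------------------
    def forward_mapping(self, z: Tensor) -> Tensor:
        # pixel-norm the latent, then the deep MLP
        x = ad.mul(z, ad.rsqrt(ad.tmean(ad.mul(z, z), axis=1, keepdims=True) + 1e-8))
        for i in range(self.config.mapping_layers):
            x = ad.add(ad.matmul(x, self.params[f"map.{i}.w"]), self.params[f"map.{i}.b"])
            x = ad.leaky_relu(x, 0.2)
        return x

    def _noise(self, noise_seed: int, layer: int, b: int, res: int) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence((noise_seed, layer, res)))
        return rng.standard_normal((b, 1, res, res)).astype(np.float32)

    def forward_synthesis(self, w: Tensor, noise_seed: int | None = 0) -> Tensor:
        """w: (B, w_dim) -> image batch (B, 1, R, R) in [-1, 1]."""
        cfg = self.config
        b = w.shape[0]
        x = ad.broadcast_to(self.params["const"], (b,) + self.params["const"].shape[1:])
        rgb = None
        for li, r in enumerate(cfg.resolutions()):
            if r > 4:
                x = ad.upsample2(x)
            style = ad.add(ad.matmul(w, self.params[f"g{r}.affine.w"]), self.params[f"g{r}.affine.b"])
            conv = ModulatedConv2d(self.params[f"g{r}.conv.w"], demodulate=True)
            x = conv(x, style)
            if cfg.noise_injection and noise_seed is not None:
                noise = Tensor(self._noise(noise_seed, li, b, r))
                x = ad.add(x, ad.mul(self.params[f"g{r}.noise"], noise))
            x = ad.leaky_relu(ad.add(x, self.params[f"g{r}.conv.b"]), 0.2)
            rgb_style = ad.add(
                ad.matmul(w, self.params[f"g{r}.rgb.affine.w"]), self.params[f"g{r}.rgb.affine.b"]
            )
            to_rgb = ModulatedConv2d(self.params[f"g{r}.rgb.w"], demodulate=False)
            layer_rgb = ad.add(to_rgb(x, rgb_style), self.params[f"g{r}.rgb.b"])
            rgb = layer_rgb if rgb is None else ad.add(ad.upsample2(rgb), layer_rgb)
        return ad.tanh(rgb)


class DiscriminatorModel:
    """Residual convolutional discriminator mapping an image to one logit."""

    def __init__(self, config: GeneratorConfig, params: dict[str, Tensor]):
        self.config = config
        self.params = params

    @classmethod
    def initialize(cls, config: GeneratorConfig, seed: int | None = None) -> "DiscriminatorModel":
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed if seed is None else seed, 0xD1))
        )
        p: dict[str, np.ndarray] = {}
        res = config.resolution
        p["from_rgb.w"] = _init_w(rng, (config.channels(res), 1, 1, 1), 1)
        p["from_rgb.b"] = np.zeros((1, config.channels(res), 1, 1), dtype=np.float32)
        r = res
        while r > 4:
            cin, cout = config.channels(r), config.channels(r // 2)
            p[f"d{r}.conv1.w"] = _init_w(rng, (cin, cin, 3, 3), cin * 9)
            p[f"d{r}.conv1.b"] = np.zeros((1, cin, 1, 1), dtype=np.float32)
            p[f"d{r}.conv2.w"] = _init_w(rng, (cout, cin, 3, 3), cin * 9)
            p[f"d{r}.conv2.b"] = np.zeros((1, cout, 1, 1), dtype=np.float32)
            p[f"d{r}.skip.w"] = _init_w(rng, (cout, cin, 1, 1), cin)
            r //= 2
        c4 = config.channels(4)
        p["final.conv.w"] = _init_w(rng, (c4, c4, 3, 3), c4 * 9)
        p["final.conv.b"] = np.zeros((1, c4, 1, 1), dtype=np.float32)
        p["final.fc1.w"] = _init_w(rng, (c4 * 16, c4), c4 * 16)
        p["final.fc1.b"] = np.zeros(c4, dtype=np.float32)
        p["final.fc2.w"] = _init_w(rng, (c4, 1), c4)
        p["final.fc2.b"] = np.zeros(1, dtype=np.float32)
        return cls(config, {k: Tensor(v, requires_grad=True) for k, v in p.items()})

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.astype(np.float32).copy()

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.shape[2] != cfg.resolution or x.shape[3] != cfg.resolution:
            raise StyleGanError(
                f"image resolution {x.shape[2:]} does not match configured {cfg.resolution}"
            )
        inv_sqrt2 = 1.0 / math.sqrt(2.0)
        h = ad.leaky_relu(
            ad.add(ad.conv2d(x, self.params["from_rgb.w"]), self.params["from_rgb.b"]), 0.2
        )
        r = cfg.resolution
        while r > 4:
            t = ad.leaky_relu(
                ad.add(ad.conv2d(h, self.params[f"d{r}.conv1.w"], pad=1), self.params[f"d{r}.conv1.b"]),
                0.2,
            )
            t = ad.leaky_relu(
                ad.add(ad.conv2d(t, self.params[f"d{r}.conv2.w"], pad=1), self.params[f"d{r}.conv2.b"]),
                0.2,
            )
            t = ad.avg_pool2(t)
            skip = ad.avg_pool2(ad.conv2d(h, self.params[f"d{r}.skip.w"]))
            h = ad.mul(ad.add(t, skip), inv_sqrt2)
            r //= 2
        h = ad.leaky_relu(
            ad.add(ad.conv2d(h, self.params["final.conv.w"], pad=1), self.params["final.conv.b"]), 0.2
        )
        b = h.shape[0]
        h = ad.reshape(h, (b, h.shape[1] * 16))
        h = ad.leaky_relu(ad.add(ad.matmul(h, self.params["final.fc1.w"]), self.params["final.fc1.b"]), 0.2)
        return ad.add(ad.matmul(h, self.params["final.fc2.w"]), self.params["final.fc2.b"])


# ---------------------------------------------------------------------------
# Public functional surface
# ---------------------------------------------------------------------------

def map_latent(z: LatentZ | np.ndarray, model: GeneratorModel) -> LatentW:
    """Deterministically map a latent z through the mapping network."""
    vec = z.vector if isinstance(z, LatentZ) else np.asarray(z, dtype=np.float32)
    if vec.shape != (model.config.z_dim,):
        raise StyleGanError(f"z has shape {vec.shape}, expected ({model.config.z_dim},)")
    with ad.no_grad():
        w = model.forward_mapping(Tensor(vec[None]))
    return LatentW(vector=w.data[0].copy())


def synthesize(w: LatentW | np.ndarray, model: GeneratorModel, noise_seed: int = 0) -> np.ndarray:
    """Render one image in [-1, 1] from an intermediate latent."""
    vec = w.vector if isinstance(w, LatentW) else np.asarray(w, dtype=np.float32)
    if vec.shape != (model.config.w_dim,):
        raise StyleGanError(f"w has shape {vec.shape}, expected ({model.config.w_dim},)")
    with ad.no_grad():
        img = model.forward_synthesis(Tensor(vec[None]), noise_seed=noise_seed)
    return img.data[0, 0].copy()


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Generator range [-1, 1] -> 8-bit, half-up rounded."""
    return np.clip(round_half_up((np.asarray(img) + 1.0) * 127.5), 0, 255).astype(np.uint8)


def discriminate(image: np.ndarray, model: DiscriminatorModel) -> np.ndarray:
    """Logit(s) for one image (R, R) or a batch (B, R, R) / (B, 1, R, R)."""
    x = np.asarray(image, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    with ad.no_grad():
        logits = model.forward(Tensor(x))
    out = logits.data[:, 0].copy()
    if not np.isfinite(out).all():
        raise StyleGanError("discriminator produced non-finite logits")
    return float(out[0]) if single else out


def gan_losses(real_logits, fake_logits) -> tuple[Tensor, Tensor]:
    """Non-saturating logistic losses:
    d = E[softplus(-real)] + E[softplus(fake)],  g = E[softplus(-fake)]."""
    rl = real_logits if isinstance(real_logits, Tensor) else Tensor(np.asarray(real_logits, dtype=np.float32))
    fl = fake_logits if isinstance(fake_logits, Tensor) else Tensor(np.asarray(fake_logits, dtype=np.float32))
    d_loss = ad.add(ad.tmean(ad.softplus(ad.mul(rl, -1.0))), ad.tmean(ad.softplus(fl)))
    g_loss = ad.tmean(ad.softplus(ad.mul(fl, -1.0)))
    return d_loss, g_loss


def minimax_value(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """The two-player game value E[log D(x)] + E[log(1 - D(G(z)))] evaluated at
    given discriminator outputs (probabilities)."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    step: int
    d_loss: float
    g_loss: float
    fid: float
    state: dict[str, np.ndarray]


@dataclass
class TrainingHistory:
    snapshots: list[Snapshot] = field(default_factory=list)
    steps: list[int] = field(default_factory=list)
    d_losses: list[float] = field(default_factory=list)
    g_losses: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        lines = ["step,d_loss,g_loss,fid"]
        fids = {s.step: s.fid for s in self.snapshots}
        for i, step in enumerate(self.steps):
            fid_s = f"{fids[step]:.6f}" if step in fids else ""
            lines.append(f"{step},{self.d_losses[i]:.6f},{self.g_losses[i]:.6f},{fid_s}")
        Path(path).write_text("\n".join(lines) + "\n")


def _dataset_to_array(dataset, resolution: int, strict: bool) -> np.ndarray:
    if len(dataset) == 0:
        raise StyleGanError("training dataset is empty")
    imgs = []
    for item in dataset:
        if isinstance(item, NormalizedImage):
            if strict and getattr(item, "is_lesioned", None):
                raise StyleGanError(
                    "strict mode: training set must contain only lesion-free images"
                )
            arr = item.pixels
        else:
            arr = np.asarray(item)
        if arr.shape != (resolution, resolution):
            raise StyleGanError(
                f"image shape {arr.shape} does not match configured resolution {resolution}"
            )
        imgs.append(arr.astype(np.float32) / 127.5 - 1.0)
    return np.stack(imgs)[:, None]  # (N, 1, R, R)


def train(
    dataset,
    config: GeneratorConfig,
    steps: int = 400,
    snapshot_interval: int = 100,
    strict: bool = True,
    n_eval: int = 64,
    embedder=None,
    progress: bool = False,
) -> tuple[GeneratorModel, TrainingHistory]:
    """Adversarial training on lesion-free images only.

    Alternates discriminator updates (non-saturating loss + R1 penalty on real
    batches) with generator updates.  A snapshot with its Fréchet distance
    against a held-out real batch is recorded at step 0, every
    ``snapshot_interval`` steps, and at the final step.
    """
    data = _dataset_to_array(dataset, config.resolution, strict)
    n = data.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7A)))
    gen = GeneratorModel.initialize(config)
    disc = DiscriminatorModel.initialize(config)
    opt_g = ad.Adam(gen.parameters(), lr=config.learning_rate, betas=(0.0, 0.99))
    opt_d = ad.Adam(disc.parameters(), lr=config.learning_rate, betas=(0.0, 0.99))

    embedder = embedder or RandomConvEmbedder(seed=config.seed)
    n_eval = min(n_eval, n)
    eval_real = to_uint8(data[:n_eval, 0])
    eval_z = np.random.default_rng(np.random.SeedSequence((config.seed, 0xE7))).standard_normal(
        (n_eval, config.z_dim)
    ).astype(np.float32)

    def snapshot_fid() -> float:
        fakes = []
        with ad.no_grad():
            for i in range(0, n_eval, config.batch_size):
                zb = Tensor(eval_z[i : i + config.batch_size])
                img = gen.forward_synthesis(gen.forward_mapping(zb), noise_seed=0)
                fakes.append(img.data[:, 0])
        return compute_fid(eval_real, to_uint8(np.concatenate(fakes)), embedder=embedder)

    history = TrainingHistory()
    last_d, last_g = math.nan, math.nan

    iterator = range(1, steps + 1)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="train", leave=False)

    for step in iterator:
        if step == 1:
            history.snapshots.append(
                Snapshot(step=0, d_loss=math.nan, g_loss=math.nan, fid=snapshot_fid(), state=gen.state_dict())
            )
        idx = rng.integers(0, n, size=config.batch_size)
        real_np = data[idx]
        z_np = rng.standard_normal((config.batch_size, config.z_dim)).astype(np.float32)
        noise_seed = int(rng.integers(0, 2**31 - 1))

        # --- discriminator step (generator frozen) ---
        with ad.no_grad():
            fake_np = gen.forward_synthesis(gen.forward_mapping(Tensor(z_np)), noise_seed=noise_seed).data
        real = Tensor(real_np, requires_grad=True)
        real_logits = disc.forward(real)
        fake_logits = disc.forward(Tensor(fake_np))
        d_loss, _ = gan_losses(real_logits, fake_logits)
        # R1: gradient penalty of the real-image logits
        if config.r1_gamma > 0:
            (gx,) = ad.grad_of(ad.tsum(real_logits), [real], create_graph=True)
            r1 = ad.tmean(ad.tsum(ad.mul(gx, gx), axis=(1, 2, 3)))
            d_total = ad.add(d_loss, ad.mul(r1, config.r1_gamma / 2.0))
        else:
            d_total = d_loss
        opt_d.zero_grad()
        d_total.backward()
        opt_d.step()

        # --- generator step (discriminator frozen) ---
        z2 = rng.standard_normal((config.batch_size, config.z_dim)).astype(np.float32)
        noise_seed2 = int(rng.integers(0, 2**31 - 1))
        fake = gen.forward_synthesis(gen.forward_mapping(Tensor(z2)), noise_seed=noise_seed2)
        g_logits = disc.forward(fake)
        _, g_loss = gan_losses(Tensor(np.zeros(1, dtype=np.float32)), g_logits)
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()

        last_d, last_g = float(d_loss.data), float(g_loss.data)
        history.steps.append(step)
        history.d_losses.append(last_d)
        history.g_losses.append(last_g)
        if step % snapshot_interval == 0 or step == steps:
            history.snapshots.append(
                Snapshot(step=step, d_loss=last_d, g_loss=last_g, fid=snapshot_fid(), state=gen.state_dict())
            )
    return gen, history


def select_best_snapshot(history: TrainingHistory, config: GeneratorConfig | None = None,
                         model: GeneratorModel | None = None) -> GeneratorModel:
    """Parameters of the minimum-FID snapshot (ties broken by earliest step).

    Monitoring the lowest Fréchet distance is the guard against mode collapse:
    a collapsed late generator scores worse than an earlier healthy one.
    """
    if not history.snapshots:
        raise StyleGanError("training history contains no snapshots")
    best = min(history.snapshots, key=lambda s: (s.fid, s.step))
    if model is not None:
        cfg = model.config
    elif config is not None:
        cfg = config
    else:
        raise StyleGanError("need a config or model to rebuild the snapshot")
    out = GeneratorModel.initialize(cfg)
    out.load_state(best.state)
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: GeneratorModel, path, step: int = 0) -> None:
    """Self-describing checkpoint: config JSON + parameters + step."""
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(asdict(model.config)).encode(), dtype=np.uint8),
        __step__=np.array(step),
        **arrays,
    )


def load_checkpoint(path) -> tuple[GeneratorModel, int]:
    with np.load(path) as data:
        cfg = GeneratorConfig(**json.loads(bytes(data["__config__"]).decode()))
        step = int(data["__step__"])
        state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    model = GeneratorModel.initialize(cfg)
    model.load_state(state)
    return model, step


# ---------------------------------------------------------------------------
# Estimator-style wrapper
# ---------------------------------------------------------------------------

class StyleGan2:
    """scikit-learn-style estimator around :func:`train`.

    Parameters mirror :class:`GeneratorConfig` plus the training budget; after
    ``fit`` the attributes ``generator_`` (minimum-FID snapshot), ``final_``
    (last-step parameters) and ``history_`` are available.
    """

    def __init__(
        self,
        resolution: int = 32,
        z_dim: int = 64,
        w_dim: int = 64,
        mapping_layers: int = 8,
        base_channels: int = 32,
        noise_injection: bool = True,
        learning_rate: float = 0.001,
        batch_size: int = 8,
        r1_gamma: float = 10.0,
        steps: int = 400,
        snapshot_interval: int = 100,
        strict: bool = True,
        seed: int = 0,
    ):
        self.resolution = resolution
        self.z_dim = z_dim
        self.w_dim = w_dim
        self.mapping_layers = mapping_layers
        self.base_channels = base_channels
        self.noise_injection = noise_injection
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.r1_gamma = r1_gamma
        self.steps = steps
        self.snapshot_interval = snapshot_interval
        self.strict = strict
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "resolution", "z_dim", "w_dim", "mapping_layers", "base_channels",
            "noise_injection", "learning_rate", "batch_size", "r1_gamma",
            "steps", "snapshot_interval", "strict", "seed",
        )}

    def set_params(self, **params) -> "StyleGan2":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> GeneratorConfig:
        return GeneratorConfig(
            z_dim=self.z_dim,
            w_dim=self.w_dim,
            mapping_layers=self.mapping_layers,
            base_channels=self.base_channels,
            resolution=self.resolution,
            noise_injection=self.noise_injection,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            r1_gamma=self.r1_gamma,
            seed=self.seed,
        )

    def fit(self, X, y=None) -> "StyleGan2":
        config = self._config()
        final, history = train(
            X, config, steps=self.steps, snapshot_interval=self.snapshot_interval, strict=self.strict
        )
        self.config_ = config
        self.final_ = final
        self.history_ = history
        self.generator_ = select_best_snapshot(history, config=config)
        return self

    def sample(self, n: int, seed: int = 0, as_uint8: bool = True) -> np.ndarray:
        """Draw n images from the fitted (minimum-FID) generator."""
        if not hasattr(self, "generator_"):
            raise StyleGanError("estimator is not fitted")
        imgs = []
        for i in range(n):
            w = map_latent(sample_z(self.config_, seed + i), self.generator_)
            img = synthesize(w, self.generator_, noise_seed=seed + i)
            imgs.append(to_uint8(img) if as_uint8 else img)
        return np.stack(imgs)
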