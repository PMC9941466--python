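import math

import numpy as np
import pytest

from mammogan import _autodiff as ad
from mammogan._autodiff import Tensor
from mammogan import stylegen
from mammogan.preprocess import NormalizedImage
from mammogan.stylegen import (
    DiscriminatorModel,
    GeneratorConfig,
    GeneratorModel,
    ModulatedConv2d,
    StyleGanError,
    TrainingHistory,
    Snapshot,
    discriminate,
    gan_losses,
    load_checkpoint,
    map_latent,
    minimax_value,
    sample_z,
    save_checkpoint,
    select_best_snapshot,
    synthesize,
    to_uint8,
    train,
)


class TestMapping:
    def test_deterministic(self, tiny_generator):
        z = sample_z(tiny_generator.config, seed=1)
        w1 = map_latent(z, tiny_generator)
        w2 = map_latent(z, tiny_generator)
        np.testing.assert_array_equal(w1.vector, w2.vector)
        assert w1.vector.shape == (tiny_generator.config.w_dim,)

    def test_default_config_has_eight_stages(self):
        cfg = GeneratorConfig(resolution=16)
        assert cfg.mapping_layers == 8
        model = GeneratorModel.initialize(cfg)
        assert model.n_mapping_stages == 8

    def test_distinct_seeds_give_distinct_w(self, tiny_generator):
        w1 = map_latent(sample_z(tiny_generator.config, seed=1), tiny_generator)
        w2 = map_latent(sample_z(tiny_generator.config, seed=2), tiny_generator)
        assert (w1.vector != w2.vector).any()

    def test_dimension_mismatch_rejected(self, tiny_generator):
        with pytest.raises(StyleGanError):
            map_latent(np.zeros(7, dtype=np.float32), tiny_generator)


class TestSynthesis:
    def test_bit_reproducible(self, tiny_generator):
        w = map_latent(sample_z(tiny_generator.config, seed=4), tiny_generator)
        a = synthesize(w, tiny_generator, noise_seed=11)
        b = synthesize(w, tiny_generator, noise_seed=11)
        np.testing.assert_array_equal(a, b)
        res = tiny_generator.config.resolution
        assert a.shape == (res, res)
        assert a.min() >= -1.0 and a.max() <= 1.0

    def test_noise_seed_changes_fine_detail_only(self, tiny_generator):
        w = map_latent(sample_z(tiny_generator.config, seed=4), tiny_generator)
        a = synthesize(w, tiny_generator, noise_seed=1)
        b = synthesize(w, tiny_generator, noise_seed=2)
        assert (a != b).any()
        # stochastic detail, not structure: images stay close
        assert np.abs(a - b).mean() < 0.25

    def test_noise_ablation_identity(self):
        cfg = GeneratorConfig(resolution=16, base_channels=16, z_dim=16, w_dim=16,
                              noise_injection=False, seed=5)
        model = GeneratorModel.initialize(cfg)
        w = map_latent(sample_z(cfg, seed=0), model)
        a = synthesize(w, model, noise_seed=1)
        b = synthesize(w, model, noise_seed=999)
        np.testing.assert_array_equal(a, b)

    def test_demodulation_style_scale_invariance(self):
        """Scaling the style vector by c > 0 must leave the demodulated
        convolution's per-channel output standard deviation invariant
        (within 5%) on white-noise input."""
        rng = np.random.default_rng(0)
        weight = Tensor(rng.standard_normal((8, 4, 3, 3)).astype(np.float32))
        conv = ModulatedConv2d(weight, demodulate=True)
        x = Tensor(rng.standard_normal((2, 4, 32, 32)).astype(np.float32))
        style = Tensor((rng.standard_normal((2, 4)) * 0.5 + 1.0).astype(np.float32))
        with ad.no_grad():
            base = conv(x, style).data
            scaled = conv(x, ad.mul(style, 7.3)).data
        sd_base = base.std(axis=(0, 2, 3))
        sd_scaled = scaled.std(axis=(0, 2, 3))
        assert np.all(np.abs(sd_scaled - sd_base) / sd_base < 0.05)

    def test_without_demodulation_scale_leaks(self):
        rng = np.random.default_rng(0)
        weight = Tensor(rng.standard_normal((8, 4, 3, 3)).astype(np.float32))
        conv = ModulatedConv2d(weight, demodulate=False)
        x = Tensor(rng.standard_normal((1, 4, 16, 16)).astype(np.float32))
        style = Tensor(np.ones((1, 4), dtype=np.float32))
        with ad.no_grad():
            sd1 = conv(x, style).data.std()
            sd2 = conv(x, ad.mul(style, 3.0)).data.std()
        assert sd2 > 2.0 * sd1


class TestDiscriminator:
    def test_deterministic_logit(self, tiny_generator):
        cfg = tiny_generator.config
        disc = DiscriminatorModel.initialize(cfg)
        rng = np.random.default_rng(1)
        img = rng.uniform(-1, 1, size=(cfg.resolution, cfg.resolution)).astype(np.float32)
        assert discriminate(img, disc) == discriminate(img, disc)

    def test_batch_of_eight_gives_eight_logits(self, tiny_generator):
        cfg = tiny_generator.config
        disc = DiscriminatorModel.initialize(cfg)
        batch = np.zeros((8, cfg.resolution, cfg.resolution), dtype=np.float32)
        logits = discriminate(batch, disc)
        assert logits.shape == (8,)

    def test_finite_on_extreme_images(self, tiny_generator):
        cfg = tiny_generator.config
        disc = DiscriminatorModel.initialize(cfg)
        for img in (np.zeros((cfg.resolution,) * 2), np.ones((cfg.resolution,) * 2)):
            assert math.isfinite(discriminate(img.astype(np.float32), disc))

    def test_shape_mismatch_rejected(self, tiny_generator):
        disc = DiscriminatorModel.initialize(tiny_generator.config)
        with pytest.raises(StyleGanError):
            discriminate(np.zeros((7, 7), dtype=np.float32), disc)


class TestLosses:
    def test_equilibrium_value_of_the_minimax_game(self):
        # D(x) = 1/2 everywhere: V = log(1/2) + log(1/2) = -2 log 2
        v = minimax_value(np.full(8, 0.5), np.full(8, 0.5))
        assert v == pytest.approx(2 * math.log(0.5), abs=1e-12)
        assert v == pytest.approx(-1.386, abs=1e-3)

    def test_perfect_discriminator_limit(self):
        d_loss, _ = gan_losses(np.full(4, 50.0), np.full(4, -50.0))
        assert float(d_loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_zero_logits_give_log2_per_term(self):
        d_loss, g_loss = gan_losses(np.zeros(3), np.zeros(3))
        assert float(d_loss.data) == pytest.approx(2 * math.log(2), rel=1e-6)
        assert float(g_loss.data) == pytest.approx(math.log(2), rel=1e-6)


def _toy_images(n, res=16, seed=0):
    rng = np.random.default_rng(seed)
    return [
        NormalizedImage(
            pixels=rng.integers(0, 256, size=(res, res)).astype(np.uint8),
            breast_mask=np.ones((res, res), dtype=bool),
            breast_area=res * res,
            is_lesioned=False,
        )
        for _ in range(n)
    ]


class TestTrain:
    def test_empty_dataset_rejected(self):
        with pytest.raises(StyleGanError):
            train([], GeneratorConfig(resolution=16))

    def test_mixed_resolution_rejected(self):
        imgs = _toy_images(2, res=16) + _toy_images(1, res=32)
        with pytest.raises(StyleGanError, match="resolution"):
            train(imgs, GeneratorConfig(resolution=16), steps=1)

    def test_strict_mode_refuses_lesioned_images(self):
        imgs = _toy_images(4, res=16)
        imgs[2].is_lesioned = True
        with pytest.raises(StyleGanError, match="lesion-free"):
            train(imgs, GeneratorConfig(resolution=16), steps=1)

    def test_seeded_runs_reproduce_loss_curves(self):
        imgs = _toy_images(8, res=16)
        cfg = GeneratorConfig(resolution=16, base_channels=16, z_dim=16, w_dim=16, seed=2)
        _, h1 = train(imgs, cfg, steps=4, snapshot_interval=4, n_eval=8)
        _, h2 = train(imgs, cfg, steps=4, snapshot_interval=4, n_eval=8)
        assert h1.d_losses == h2.d_losses
        assert h1.g_losses == h2.g_losses
        assert [s.fid for s in h1.snapshots] == [s.fid for s in h2.snapshots]


class TestSnapshotSelection:
    def _history(self, fids):
        cfg = GeneratorConfig(resolution=16, base_channels=16, z_dim=16, w_dim=16)
        model = GeneratorModel.initialize(cfg)
        snaps = []
        for i, f in enumerate(fids):
            state = model.state_dict()
            state["const"] = state["const"] + i  # make snapshots distinguishable
            snaps.append(Snapshot(step=i * 10, d_loss=0.0, g_loss=0.0, fid=f, state=state))
        return TrainingHistory(snapshots=snaps), cfg

    def test_picks_minimum_fid(self):
        hist, cfg = self._history([30.0, 12.0, 9.0, 15.0])
        best = select_best_snapshot(hist, config=cfg)
        np.testing.assert_array_equal(best.params["const"].data, hist.snapshots[2].state["const"])

    def test_single_snapshot(self):
        hist, cfg = self._history([42.0])
        best = select_best_snapshot(hist, config=cfg)
        np.testing.assert_array_equal(best.params["const"].data, hist.snapshots[0].state["const"])

    def test_tie_breaks_to_earlier_step(self):
        hist, cfg = self._history([9.0, 9.0])
        best = select_best_snapshot(hist, config=cfg)
        np.testing.assert_array_equal(best.params["const"].data, hist.snapshots[0].state["const"])

    def test_empty_history_rejected(self):
        with pytest.raises(StyleGanError):
            select_best_snapshot(TrainingHistory(), config=GeneratorConfig(resolution=16))


class TestCheckpoint:
    def test_round_trip(self, tiny_generator, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_generator, path, step=123)
        loaded, step = load_checkpoint(path)
        assert step == 123
        assert loaded.config == tiny_generator.config
        w = map_latent(sample_z(loaded.config, seed=9), loaded)
        np.testing.assert_array_equal(
            synthesize(w, loaded, noise_seed=3),
            synthesize(map_latent(sample_z(tiny_generator.config, seed=9), tiny_generator),
                       tiny_generator, noise_seed=3),
        )


class TestUint8Conversion:
    def test_range_endpoints(self):
        np.testing.assert_array_equal(
            to_uint8(np.array([-1.0, 0.0, 1.0])), np.array([0, 128, 255], dtype=np.uint8)
        )  # 0.0 maps to 127.5, half-up 128


class TestEstimator:
    def test_get_set_params_round_trip(self):
        est = stylegen.StyleGan2(resolution=16, steps=2)
        params = est.get_params()
        assert params["resolution"] == 16
        est.set_params(steps=5)
        assert est.steps == 5
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_sets_fitted_attributes_and_samples(self):
        imgs = _toy_images(8, res=16)
        est = stylegen.StyleGan2(
            resolution=16, base_channels=16, z_dim=16, w_dim=16,
            steps=3, snapshot_interval=3, seed=1,
        )
        est.fit(imgs)
        assert hasattr(est, "generator_") and hasattr(est, "history_")
        out = est.sample(2, seed=0)
        assert out.shape == (2, 16, 16)
        assert out.dtype == np.uint8
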