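"""Conditional GAN: architecture contracts, objective, training, inference."""

import warnings

import numpy as np
import pytest

from tieqpi.data import denormalize_tile
from tieqpi.gan import (
    GanConfig,
    PatchDiscriminator,
    UNetGenerator,
    cgan_step,
    infer,
    load_model,
    save_model,
    train,
)
from tieqpi.gan import nn
from tieqpi.quality import MetricsConfig, ssim


def small_config(**kw):
    defaults = dict(tile=32, base_channels=4, epochs=1, batch_size=2, seed=0)
    defaults.update(kw)
    return GanConfig(**defaults)


@pytest.fixture
def small_generator():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return UNetGenerator(small_config())


class TestGeneratorArchitecture:
    def test_output_shape_and_range(self, small_generator):
        x = np.random.default_rng(0).standard_normal((2, 1, 32, 32)).astype(np.float32)
        y = small_generator.forward(x, train=True)
        assert y.shape == (2, 1, 32, 32)
        assert y.min() >= -1.0 and y.max() <= 1.0  # tanh output

    def test_encoder_halves_spatial_size_each_stage(self, small_generator):
        x = np.zeros((1, 1, 32, 32), dtype=np.float32)
        sizes = []
        for blk in small_generator.enc:
            x = blk.forward(x, train=True)
            sizes.append(x.shape[-1])
        assert sizes == [16, 8, 4, 2, 1]

    def test_full_depth_halving_plan_for_256_tiles(self):
        # 256 = 2^8: eight stages reach 128, 64, ..., 1 (checked
        # arithmetically; a 256 px network is too large for unit tests)
        cfg = GanConfig(tile=256, base_channels=1, seed=0)
        assert cfg.effective_depth == 8
        sizes = [256 // 2 ** (i + 1) for i in range(8)]
        assert sizes == [128, 64, 32, 16, 8, 4, 2, 1]

    def test_reduced_depth_warns_on_small_tiles(self):
        with pytest.warns(UserWarning, match="depth reduced"):
            UNetGenerator(small_config())

    def test_inference_is_deterministic(self, small_generator):
        x = np.random.default_rng(1).standard_normal((1, 1, 32, 32)).astype(np.float32)
        a = small_generator.predict(x)
        b = small_generator.predict(x)
        np.testing.assert_array_equal(a, b)

    def test_dropout_noise_mode_varies_output(self, small_generator):
        x = np.random.default_rng(1).standard_normal((1, 1, 32, 32)).astype(np.float32)
        a = small_generator.predict(x, noise=True)
        b = small_generator.predict(x, noise=True)
        assert not np.array_equal(a, b)


class TestDiscriminator:
    def test_score_map_in_unit_interval_and_coarse(self):
        d = PatchDiscriminator(small_config())
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 32, 32)).astype(np.float32)
        y = rng.standard_normal((2, 1, 32, 32)).astype(np.float32)
        s = d.forward(x, y)
        assert np.all((0 < s) & (s < 1))
        # three stride-2 stages (32 -> 4) then two stride-1 4x4 convs
        assert s.shape == (2, 1, 2, 2)
        assert s.shape[-1] < 32

    def test_five_convolution_stages(self):
        d = PatchDiscriminator(small_config())
        n_convs = sum(1 for l in d.net.layers if isinstance(l, nn.Conv2d))
        assert n_convs == 5

    def test_mismatched_pair_shapes_rejected(self):
        d = PatchDiscriminator(small_config())
        with pytest.raises(ValueError, match="pair shapes"):
            d.forward(np.zeros((1, 1, 32, 32)), np.zeros((1, 1, 16, 16)))


class TestObjective:
    def test_frozen_halfway_discriminator_gives_log2_per_patch(self):
        # if D outputs 0.5 everywhere the adversarial generator loss is
        # -log(0.5) per patch element
        logits = np.zeros((2, 1, 3, 3), dtype=np.float32)  # sigmoid -> 0.5
        loss, _ = nn.bce_with_logits(logits, np.ones_like(logits))
        assert loss == pytest.approx(-np.log(0.5), abs=1e-7)

    def test_perfect_generator_has_zero_l1(self, smoke_dataset):
        pair = smoke_dataset.train[0]
        diff = pair.phase_tile - pair.phase_tile
        assert np.abs(diff).mean() == 0.0

    def test_cgan_step_returns_finite_losses(self, smoke_dataset):
        cfg = GanConfig(tile=64, base_channels=4, epochs=1, batch_size=2, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = UNetGenerator(cfg)
        d = PatchDiscriminator(cfg)
        rec = cgan_step(g, d, smoke_dataset.train[:2], cfg)
        assert set(rec) == {"d_loss", "g_adv", "g_l1", "g_total"}
        assert all(np.isfinite(v) for v in rec.values())

    def test_zero_l1_weight_reduces_to_adversarial_objective(self, smoke_dataset):
        cfg = GanConfig(
            tile=64, base_channels=4, epochs=1, batch_size=2, l1_weight=0.0, seed=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = UNetGenerator(cfg)
        d = PatchDiscriminator(cfg)
        rec = cgan_step(g, d, smoke_dataset.train[:2], cfg)
        assert rec["g_total"] == pytest.approx(rec["g_adv"])


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, smoke_dataset, optics20):
        model = train(smoke_dataset, small_config(tile=64, epochs=0))
        assert model.history == []

    def test_smoke_training_l1_decreases(self, smoke_model):
        """50 pairs, 5 epochs: reconstruction loss falls epoch 1 -> 5."""
        hist = smoke_model.history
        assert len(hist) == 5
        assert hist[-1]["g_l1"] < hist[0]["g_l1"]

    def test_training_is_deterministic(self, optics20):
        from tieqpi.data import build_pairs
        from tieqpi.ensembles import bead_ensemble, simulate_training_set

        fields = bead_ensemble(4, (32, 32), optics20, seed=8)
        stacks, phases = simulate_training_set(fields, [-15.0, 0.0, 15.0], optics20)
        ds = build_pairs(stacks, phases, "all", (6, 3, 3), seed=0)
        runs = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = train(ds, small_config(epochs=2))
            runs.append(m.history[-1]["val_ssim"])
        assert runs[0] == runs[1]

    def test_discriminator_scores_real_above_generated(
        self, smoke_model, smoke_dataset
    ):
        """After training, real pairs outscore the generator's outputs."""
        d = smoke_model.discriminator
        g = smoke_model.generator
        reals, fakes = [], []
        for pair in smoke_dataset.train[:8]:
            x = pair.intensity_tile[None, None].astype(np.float32)
            y = pair.phase_tile[None, None].astype(np.float32)
            reals.append(d.forward(x, y).mean())
            fakes.append(d.forward(x, g.predict(x)).mean())
        assert np.mean(reals) > np.mean(fakes)


class TestInference:
    def test_infer_returns_phase_map_in_radians(self, smoke_model, smoke_dataset):
        pair = smoke_dataset.test[0]
        frame = denormalize_tile(pair.intensity_tile, pair.intensity_norm)
        pm = infer(smoke_model, frame)
        assert pm.phase_rad.shape == (64, 64)
        lo, hi = smoke_model.phase_range
        assert pm.phase_rad.min() >= lo - 1e-6 and pm.phase_rad.max() <= hi + 1e-6

    def test_constant_frame_gives_finite_output(self, smoke_model):
        pm = infer(smoke_model, np.full((64, 64), 3.0))
        assert np.all(np.isfinite(pm.phase_rad))

    def test_undersized_frame_rejected(self, smoke_model):
        with pytest.raises(ValueError, match="smaller"):
            infer(smoke_model, np.ones((32, 32)))

    def test_training_improves_fit_on_own_training_pair(
        self, smoke_model, smoke_model_untrained, smoke_dataset
    ):
        cfg = MetricsConfig()
        pair = smoke_dataset.train[0]

        def score(model):
            pred = model.generator.predict(pair.intensity_tile[None, None])[0, 0]
            return ssim((pred + 1) * 127.5, (pair.phase_tile + 1) * 127.5, cfg)

        assert score(smoke_model) > score(smoke_model_untrained)


class TestSerialization:
    def test_round_trip_bit_identical_inference(self, smoke_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(smoke_model, path)
        back = load_model(path)
        x = np.random.default_rng(5).uniform(-1, 1, (1, 1, 64, 64)).astype(np.float32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            np.testing.assert_array_equal(
                smoke_model.generator.predict(x), back.generator.predict(x)
            )
        assert back.history == smoke_model.history
        assert back.phase_range == pytest.approx(smoke_model.phase_range)
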