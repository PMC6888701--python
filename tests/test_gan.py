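"""Conditional GAN: architecture laws, content loss, missing-class synthesis."""

import numpy as np
import pytest

from rootcount import gan as g
from rootcount import maskops, synthdata
from rootcount.nn import autograd as ag
from tests.oracles import flood_fill_count


class TestSpecDefaults:
    def test_block_lists(self):
        spec = g.GanSpec()
        assert spec.encoder_filters == (64, 128, 256, 512, 512, 512, 512, 512, 512, 512)
        assert spec.decoder_filters == (512, 512, 512, 512, 512, 512, 256, 128, 64)
        assert spec.disc_filters == (64, 128, 256, 512)
        assert spec.kernel == 4 and spec.stride == 2

    def test_train_config_defaults(self):
        cfg = g.TrainConfig()
        assert (cfg.lr, cfg.beta1, cfg.beta2) == (2e-4, 0.5, 0.999)
        assert (cfg.epochs, cfg.batch_size) == (900, 2)


class TestGeneratorShapes:
    @pytest.mark.parametrize("hw", [(32, 32), (64, 96)])
    def test_output_preserves_input_dims(self, hw, tiny_gan_spec):
        gen = g.instantiate_generator(g.build_generator(tiny_gan_spec, hw), seed=0)
        gen.eval()
        x = np.zeros((1, 1) + hw, dtype=np.float32)
        out = gen(ag.Tensor(x)).data
        assert out.shape == (1, 3) + hw

    def test_output_in_unit_range_on_empty_mask(self, tiny_gan_spec):
        gen = g.instantiate_generator(g.build_generator(tiny_gan_spec, (32, 32)), seed=0)
        gen.eval()
        out = gen(ag.Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32))).data
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_encoder_filter_sequence_follows_capped_spec(self):
        ms = g.build_generator(g.GanSpec(), (256, 256))
        enc = [c.c_out for c in ms.convs if c.name.startswith("enc")]
        assert enc == list(g.GanSpec().encoder_filters[:ms.config["n_down"]])

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            g.build_generator(g.GanSpec(), (2, 2))


class TestDiscriminatorShapes:
    def test_patch_grid_is_input_over_sixteen(self):
        ms = g.build_discriminator(g.GanSpec(), (256, 256))
        assert tuple(ms.config["patch_grid"]) == (16, 16)
        disc = g.instantiate_discriminator(ms, seed=0)
        disc.eval()
        out = disc(ag.Tensor(np.zeros((2, 4, 256, 256), dtype=np.float32))).data
        assert out.shape == (2, 1, 16, 16)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            g.build_discriminator(g.GanSpec(), (100, 100))

    def test_sigmoid_readout_is_probability(self, tiny_gan_spec):
        ms = g.build_discriminator(tiny_gan_spec, (32, 32))
        disc = g.instantiate_discriminator(ms, seed=0)
        disc.eval()
        logits = disc(ag.Tensor(np.random.default_rng(0).random(
            (1, 4, 32, 32), dtype=np.float32)))
        probs = ag.sigmoid(logits).data
        assert ((0 <= probs) & (probs <= 1)).all()


class TestContentLoss:
    def test_identical_inputs_zero(self):
        x = np.random.default_rng(0).random((1, 3, 16, 16), dtype=np.float32)
        for mode in ("mse_pixels", "random_features"):
            assert float(g.content_loss(x, x, mode).data) == pytest.approx(0.0, abs=1e-10)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        a = rng.random((1, 3, 16, 16), dtype=np.float32)
        b = rng.random((1, 3, 16, 16), dtype=np.float32)
        for mode in ("mse_pixels", "random_features"):
            assert float(g.content_loss(a, b, mode).data) >= 0.0

    def test_pixel_mode_equals_hand_computed_mse(self):
        rng = np.random.default_rng(2)
        a = rng.random((2, 3, 8, 8), dtype=np.float32)
        b = rng.random((2, 3, 8, 8), dtype=np.float32)
        assert float(g.content_loss(a, b, "mse_pixels").data) == \
            pytest.approx(float(np.mean((a - b) ** 2)), rel=1e-6)

    def test_vgg_mode_falls_back_with_warning(self, caplog):
        import logging
        x = np.zeros((1, 3, 8, 8), dtype=np.float32)
        with caplog.at_level(logging.WARNING, logger="rootcount.gan"):
            loss = g.content_loss(x, x, "vgg19_features")
        assert "falling back" in caplog.text
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            g.content_loss(np.zeros((1, 3, 8, 8)), np.zeros((1, 3, 4, 4)), "mse_pixels")


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self, gan_manifest, tiny_gan_spec):
        gen_ms = g.build_generator(tiny_gan_spec, (32, 32))
        disc_ms = g.build_discriminator(tiny_gan_spec, (32, 32))
        cfg = g.TrainConfig(epochs=0, batch_size=2, seed=4)
        gen, disc, hist = g.train_gan(gen_ms, disc_ms, gan_manifest, cfg, tiny_gan_spec)
        fresh = g.instantiate_generator(gen_ms, seed=4)
        for a, b in zip(gen.net.state_arrays(), fresh.state_arrays()):
            assert np.array_equal(a, b)
        assert hist["epoch"] == []

    def test_empty_manifest_rejected(self, tiny_gan_spec):
        import pandas as pd
        empty = pd.DataFrame({"path_image": [], "path_mask": [], "split": []})
        gen_ms = g.build_generator(tiny_gan_spec, (32, 32))
        disc_ms = g.build_discriminator(tiny_gan_spec, (32, 32))
        with pytest.raises(ValueError):
            g.train_gan(gen_ms, disc_ms, empty, g.TrainConfig(epochs=1), tiny_gan_spec)


@pytest.fixture(scope="module")
def library():
    cfg = synthdata.old_preset(128, 96)
    entries = []
    for i, k in enumerate([2, 3]):
        s = synthdata.generate_sample(cfg, k, rng_seed=40 + i)
        entries.append((s.mask, k))
    return maskops.MaskLibrary(entries=entries)


@pytest.fixture(scope="module")
def untrained_gen(tiny_gan_spec):
    ms = g.build_generator(tiny_gan_spec, (32, 32))
    from rootcount.modelspec import TrainedModel
    return TrainedModel(spec=ms, net=g.instantiate_generator(ms, seed=0).eval())


class TestMissingClassSynthesis:
    def test_target_five_from_two_and_three(self, untrained_gen, library):
        samples = g.generate_for_missing_class(untrained_gen, library, 5, 4, seed=1)
        assert len(samples) == 4
        for s in samples:
            assert s.count == 5
            assert s.provenance == "gan"
            # fully-convolutional generator keeps the native mask resolution
            assert s.image.shape == (96, 128, 3)
            assert flood_fill_count(s.mask) == 5

    def test_zero_samples_requested(self, untrained_gen, library):
        assert g.generate_for_missing_class(untrained_gen, library, 5, 0, seed=1) == []

    def test_conditioning_masks_have_target_components(self, library):
        for seed in range(5):
            mask = maskops.combine_masks(library, 5, rng_seed=seed)
            assert flood_fill_count(mask) == 5
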