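"""Classifier architecture, parameter accounting, augmentation, training."""

import numpy as np
import pytest

from rootcount import classify_models as cm
from rootcount import synthdata
from rootcount.modelspec import ModelSpec, TrainedModel, separable_param_count, standard_param_count
from rootcount.nn import autograd as ag
from tests.conftest import small_classifier_spec


class TestParamCounts:
    def test_3x3_64_to_64_exact_values(self):
        assert standard_param_count(3, 64, 64) == 36864
        assert separable_param_count(3, 64, 64) == 4672

    def test_1x1_separation_is_counterproductive(self):
        assert standard_param_count(1, 32, 48) == 32 * 48
        assert separable_param_count(1, 32, 48) == 32 + 32 * 48

    def test_ratio_limit(self):
        k, c = 3, 512
        ratio = separable_param_count(k, c, c) / standard_param_count(k, c, c)
        assert ratio == pytest.approx(1 / c + 1 / k**2, rel=1e-6)

    def test_every_spatial_conv_shrinks_in_default_spec(self):
        ms = cm.build_classifier(cm.ClassifierSpec())
        spatial = [c for c in ms.convs if c.k > 1]
        assert spatial, "default spec must contain spatial convolutions"
        for c in spatial:
            assert separable_param_count(c.k, c.c_in, c.c_out) < \
                standard_param_count(c.k, c.c_in, c.c_out)

    def test_separable_model_smaller_than_standard(self):
        sep = cm.build_classifier(cm.ClassifierSpec(conv_kind="separable"))
        std = cm.build_classifier(cm.ClassifierSpec(conv_kind="standard"))
        assert sep.param_count() < std.param_count()
        # the instantiated networks agree with the analytic ordering
        n_sep = cm.instantiate(sep).num_params()
        n_std = cm.instantiate(std).num_params()
        assert n_sep < n_std


class TestBuildClassifier:
    @pytest.mark.parametrize("arity", [2, 7])
    def test_softmax_head_arity(self, arity):
        spec = cm.ClassifierSpec(input_size=32, dense_block_lengths=(1, 1, 1, 1),
                                 growth_rate=4, stem_filters=8, output_arity=arity)
        net = cm.instantiate(cm.build_classifier(spec))
        net.eval()
        x = np.random.default_rng(0).random((3, 3, 32, 32), dtype=np.float32)
        logits = net(ag.Tensor(x)).data
        assert logits.shape == (3, arity)
        probs = ag.softmax(logits, axis=1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_block_structure_is_validated(self):
        with pytest.raises(ValueError):
            cm.ClassifierSpec(dense_block_lengths=(3, 6, 12))
        with pytest.raises(ValueError):
            cm.ClassifierSpec(output_arity=1)

    def test_spec_roundtrips_through_json(self):
        ms = cm.build_classifier(cm.ClassifierSpec(output_arity=7))
        back = ModelSpec.from_json(ms.to_json())
        assert back.output_arity == 7
        assert back.param_count() == ms.param_count()


class TestAugmentPolicy:
    def test_defaults(self):
        p = cm.AugmentPolicy()
        assert p.zoom_range == 0.2
        assert p.brightness_range == (0.2, 1.0)
        assert p.rotation_range == 10.0
        assert p.horizontal_flip is True

    def test_augment_preserves_shape_and_range(self):
        rng = np.random.default_rng(0)
        img = rng.random((48, 48, 3)).astype(np.float32)
        for _ in range(5):
            out = cm.augment_image(img, cm.AugmentPolicy(), rng)
            assert out.shape == img.shape
            assert out.min() >= 0.0 and out.max() <= 1.0


class _FixedLogitsNet:
    def __init__(self, logits):
        self.logits = np.asarray(logits, dtype=np.float32)

    def eval(self):
        return self

    def __call__(self, x):
        return ag.Tensor(np.tile(self.logits, (x.data.shape[0], 1)))


def _stub_model(logits):
    spec = ModelSpec(kind="densenet", input_size=(8, 8), in_channels=3,
                     output_arity=len(logits))
    return TrainedModel(spec=spec, net=_FixedLogitsNet(logits))


class TestPredictClass:
    def test_argmax_label(self):
        label, probs = cm.predict_class(_stub_model([0.1, 0.9]), np.zeros((8, 8, 3)))
        assert label == 1
        assert probs.sum() == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_index(self):
        label, _ = cm.predict_class(_stub_model([0.5, 0.5]), np.zeros((8, 8, 3)))
        assert label == 0

    def test_seven_way_labels_in_range(self):
        label, probs = cm.predict_class(_stub_model(list(range(7))), np.zeros((8, 8, 3)))
        assert probs.shape == (7,)
        assert 0 <= label <= 6

    def test_rejects_non_rgb_input(self):
        with pytest.raises(ValueError):
            cm.predict_class(_stub_model([0.0, 1.0]), np.zeros((8, 8)))


@pytest.fixture(scope="module")
def tiny_manifest(tmp_path_factory):
    cfg = synthdata.old_preset(32, 32, storage_width_range=(4, 6),
                               fibrous_count_range=(0, 2), min_separation=3.0)
    man = synthdata.generate_dataset({"old": cfg}, {1: 8, 2: 8}, 3,
                                     str(tmp_path_factory.mktemp("tiny")))
    return synthdata.split_manifest(man, 3)


class TestTrainClassifier:
    def _spec(self):
        return cm.build_classifier(cm.ClassifierSpec(
            input_size=32, dense_block_lengths=(1, 1, 1, 1), growth_rate=4,
            stem_filters=8, output_arity=3))

    def test_zero_epochs_gives_untrained_model_empty_history(self, tiny_manifest):
        tr = cm.train_classifier(self._spec(), tiny_manifest, None, epochs=0,
                                 batch_size=4, seed=0, label_column="count")
        assert tr.history["epoch"] == []
        fresh = cm.instantiate(self._spec(), seed=0)
        for a, b in zip(tr.net.state_arrays(), fresh.state_arrays()):
            assert np.array_equal(a, b)

    def test_deterministic_under_fixed_seed(self, tiny_manifest):
        runs = [cm.train_classifier(self._spec(), tiny_manifest, None, epochs=2,
                                    batch_size=4, seed=7, label_column="count")
                for _ in range(2)]
        assert runs[0].history["train_loss"] == runs[1].history["train_loss"]

    def test_label_exceeding_arity_raises(self, tiny_manifest):
        bad = cm.build_classifier(cm.ClassifierSpec(
            input_size=32, dense_block_lengths=(1, 1, 1, 1), growth_rate=4,
            stem_filters=8, output_arity=2))
        with pytest.raises(ValueError, match="arity"):
            cm.train_classifier(bad, tiny_manifest, None, epochs=1,
                                batch_size=4, seed=0, label_column="count")


def test_learning_curve_is_recorded(trained_age_model):
    h = trained_age_model.history
    assert len(h["epoch"]) == 10
    assert all(0 <= a <= 1 for a in h["val_acc"])
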