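"""Shared fixtures: small procedural datasets and toy-scale trained models.

The heavy fixtures are session-scoped so each network is trained exactly
once per test run.  All dataset and training seeds are fixed constants.
"""

import numpy as np
import pandas as pd
import pytest

from rootcount import classify_models as cm
from rootcount import gan as rcgan
from rootcount import segment_models as sm
from rootcount import synthdata

S = 64  # toy image side


def small_classifier_spec(arity):
    return cm.build_classifier(cm.ClassifierSpec(
        input_size=S, dense_block_lengths=(1, 1, 1, 1), growth_rate=16,
        stem_filters=16, output_arity=arity))


def easy_old_preset(side=S):
    """Thick, bright, well-separated storage roots; sparse fibrous roots."""
    return synthdata.old_preset(
        side, side, storage_width_range=(7.5, 9.0), occlusion_density=0.0,
        fibrous_count_range=(2, 4), noise_sigma=0.01,
        storage_brightness=(0.65, 0.8), min_separation=4.0)


def easy_young_preset(side=S):
    """Thinner, dimmer roots with more fibrous distractors — age is obvious
    from brightness and clutter while counts stay easy."""
    return synthdata.young_preset(
        side, side, storage_width_range=(5.5, 7.0), occlusion_density=0.0,
        fibrous_count_range=(5, 9), noise_sigma=0.01,
        storage_brightness=(0.42, 0.52), min_separation=4.0)


def occluded_young_preset(side=S):
    """The hard regime: overlap allowed, dense fibrous occlusion."""
    return synthdata.young_preset(
        side, side, storage_width_range=(5.5, 7.0), occlusion_density=0.6,
        fibrous_count_range=(20, 30), noise_sigma=0.02, allow_overlap=True,
        min_separation=4.0)


@pytest.fixture(scope="session")
def easy_manifest(tmp_path_factory):
    """Mixed-age easy dataset: counts 1-3, 60 samples per count per age."""
    out = tmp_path_factory.mktemp("easy_ds")
    man = synthdata.generate_dataset(
        {"old": easy_old_preset(), "young": easy_young_preset()},
        {1: 60, 2: 60, 3: 60}, rng_seed=99, out_dir=str(out))
    return synthdata.split_manifest(man, rng_seed=99)


@pytest.fixture(scope="session")
def trained_age_model(easy_manifest):
    return cm.train_classifier(small_classifier_spec(2), easy_manifest, None,
                               epochs=10, batch_size=8, seed=0, lr=3e-3,
                               label_column="age")


@pytest.fixture(scope="session")
def trained_count_models(easy_manifest):
    old = cm.train_classifier(small_classifier_spec(4),
                              easy_manifest[easy_manifest["age"] == "old"], None,
                              epochs=35, batch_size=8, seed=1, lr=3e-3,
                              label_column="count")
    young = cm.train_classifier(small_classifier_spec(4),
                                easy_manifest[easy_manifest["age"] == "young"], None,
                                epochs=35, batch_size=8, seed=2, lr=3e-3,
                                label_column="count")
    return old, young


@pytest.fixture(scope="session")
def trained_segmenter(easy_manifest):
    """Lite-SegNet trained on a class-balanced subset of the easy set."""
    tr = easy_manifest[easy_manifest["split"] == "train"].groupby(
        ["age", "count"], group_keys=False).head(17)
    va = easy_manifest[easy_manifest["split"] == "val"].groupby(
        ["age", "count"], group_keys=False).head(3)
    spec = sm.SegNetSpec(input_width=S, input_height=S,
                         filters_per_block=(16, 32, 64, 64),
                         convs_per_block=(2, 2, 3, 3))
    return sm.train_segmenter(sm.build_segnet(spec), pd.concat([tr, va]),
                              epochs=8, batch_size=2, seed=0, lr=3e-3)


@pytest.fixture(scope="session")
def occluded_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("hard_ds")
    man = synthdata.generate_dataset({"young": occluded_young_preset()},
                                     {1: 8, 2: 8, 3: 8}, rng_seed=5, out_dir=str(out))
    man["split"] = "test"
    return man


# ------------------------------------------------------------- GAN fixtures

GAN_SIDE = 32


@pytest.fixture(scope="session")
def gan_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("gan_ds")
    cfg = synthdata.old_preset(GAN_SIDE, GAN_SIDE, storage_width_range=(4.0, 6.0),
                               occlusion_density=0.05, fibrous_count_range=(2, 5),
                               noise_sigma=0.01, min_separation=3.0)
    man = synthdata.generate_dataset({"old": cfg}, {1: 12, 2: 12, 3: 8},
                                     rng_seed=33, out_dir=str(out))
    return synthdata.split_manifest(man, rng_seed=33)


@pytest.fixture(scope="session")
def tiny_gan_spec():
    return rcgan.GanSpec(encoder_filters=(32, 64, 128, 128, 128),
                         decoder_filters=(128, 128, 128, 64, 32),
                         disc_filters=(32, 64), content_net="random_features",
                         lambda_content=100.0)


@pytest.fixture(scope="session")
def trained_gan(gan_manifest, tiny_gan_spec):
    gen_ms = rcgan.build_generator(tiny_gan_spec, (GAN_SIDE, GAN_SIDE))
    disc_ms = rcgan.build_discriminator(tiny_gan_spec, (GAN_SIDE, GAN_SIDE))
    cfg = rcgan.TrainConfig(epochs=30, batch_size=2, seed=0)
    gen, disc, history = rcgan.train_gan(gen_ms, disc_ms, gan_manifest, cfg, tiny_gan_spec)
    return gen, disc, history


@pytest.fixture(scope="session")
def gan_judge_segmenter(gan_manifest):
    spec = sm.SegNetSpec(input_width=GAN_SIDE, input_height=GAN_SIDE,
                         filters_per_block=(16, 32, 64, 64),
                         convs_per_block=(2, 2, 3, 3))
    return sm.train_segmenter(sm.build_segnet(spec), gan_manifest,
                              epochs=10, batch_size=2, seed=0, lr=3e-3)
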