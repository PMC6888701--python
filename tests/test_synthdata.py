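"""Procedural generator: determinism, mask-count fidelity, dataset plumbing."""

import numpy as np
import pytest
from scipy import ndimage

from rootcount import io as rcio
from rootcount import synthdata
from tests.oracles import flood_fill_count


@pytest.fixture(scope="module")
def old_cfg():
    return synthdata.old_preset(160, 120)


class TestGenerateSample:
    def test_zero_count_gives_empty_mask(self, old_cfg):
        s = synthdata.generate_sample(old_cfg, 0, rng_seed=1)
        assert not s.mask.any()

    def test_component_count_matches_label(self, old_cfg):
        s = synthdata.generate_sample(old_cfg, 3, rng_seed=7)
        assert flood_fill_count(s.mask) == 3

    def test_deterministic_given_seed(self, old_cfg):
        a = synthdata.generate_sample(old_cfg, 2, rng_seed=5)
        b = synthdata.generate_sample(old_cfg, 2, rng_seed=5)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_image_values_in_unit_range(self, old_cfg):
        s = synthdata.generate_sample(old_cfg, 4, rng_seed=3)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0
        assert s.image.shape[:2] == s.mask.shape

    def test_count_outside_range_rejected(self, old_cfg):
        with pytest.raises(ValueError, match="outside"):
            synthdata.generate_sample(old_cfg, 9, rng_seed=0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synthdata.SynthConfig(count_range=(-1, 3))
        with pytest.raises(ValueError):
            synthdata.SynthConfig(image_width=0)
        with pytest.raises(ValueError):
            synthdata.SynthConfig(age_class="middle")


class TestAgePresets:
    def test_young_thinner_and_more_occluded_than_old(self):
        young = synthdata.young_preset()
        old = synthdata.old_preset()
        assert np.mean(young.storage_width_range) < np.mean(old.storage_width_range)
        assert young.occlusion_density > old.occlusion_density

    def test_storage_roots_visibly_wider_in_old_samples(self):
        """Mean storage-root pixel width (2x the Euclidean distance
        transform averaged over foreground) separates the age classes."""
        widths = {}
        for name, preset in [("old", synthdata.old_preset),
                             ("young", synthdata.young_preset)]:
            cfg = preset(128, 96)
            vals = []
            for seed in range(50):
                s = synthdata.generate_sample(cfg, 1 + seed % 3, rng_seed=seed)
                edt = ndimage.distance_transform_edt(s.mask)
                vals.append(2.0 * edt[s.mask].mean())
            widths[name] = np.mean(vals)
        assert widths["old"] > widths["young"]


class TestGenerateDataset:
    def test_cardinality_and_missing_class(self, tmp_path):
        cfg = synthdata.old_preset(96, 72)
        man = synthdata.generate_dataset({"old": cfg}, {0: 2, 1: 2, 2: 2, 5: 0},
                                         rng_seed=3, out_dir=str(tmp_path))
        assert sorted(man["count"]) == [0, 0, 1, 1, 2, 2]
        assert (man["count"] == 5).sum() == 0

    def test_same_seed_identical_bytes(self, tmp_path):
        cfg = synthdata.old_preset(96, 72)
        m1 = synthdata.generate_dataset({"old": cfg}, {1: 2}, 11, str(tmp_path / "a"))
        m2 = synthdata.generate_dataset({"old": cfg}, {1: 2}, 11, str(tmp_path / "b"))
        for p1, p2 in zip(m1["path_image"], m2["path_image"]):
            assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_masks_roundtrip_through_png(self, tmp_path):
        cfg = synthdata.old_preset(96, 72)
        man = synthdata.generate_dataset({"old": cfg}, {2: 1}, 4, str(tmp_path))
        s = synthdata.generate_sample(cfg, 2, int(np.random.SeedSequence(
            [4, 0, 2, 0]).generate_state(1)[0] % (2**31)))
        assert np.array_equal(rcio.read_mask_png(man.iloc[0]["path_mask"]), s.mask)


class TestSplitManifest:
    def test_80_20_split_of_100(self, tmp_path):
        import pandas as pd
        man = pd.DataFrame({"sample_id": range(100), "path_image": "", "path_mask": "",
                            "count": 1, "age": "old", "provenance": "procedural",
                            "split": ""})
        out = synthdata.split_manifest(man, rng_seed=0)
        vc = out["split"].value_counts()
        assert vc["test"] == 20 and vc["val"] == 16 and vc["train"] == 64

    def test_round_half_up_on_10_rows(self):
        import pandas as pd
        man = pd.DataFrame({"sample_id": range(10), "count": 1, "age": "old"})
        out = synthdata.split_manifest(man, rng_seed=0)
        vc = out["split"].value_counts()
        assert vc["test"] == 2 and vc["val"] == 2 and vc["train"] == 6

    @pytest.mark.parametrize("n", [3, 7, 13, 50, 101])
    def test_split_is_a_partition(self, n):
        import pandas as pd
        man = pd.DataFrame({"sample_id": range(n), "count": 1, "age": "old"})
        out = synthdata.split_manifest(man, rng_seed=1)
        assert set(out["split"]) <= {"train", "val", "test"}
        assert len(out) == n
        assert out["sample_id"].is_unique

    def test_too_few_rows_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError, match="at least 3"):
            synthdata.split_manifest(pd.DataFrame({"sample_id": [1, 2]}), 0)
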