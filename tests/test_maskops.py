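"""Mask operations: component counting, denoising, conditioning-mask synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk

from rootcount import maskops, synthdata
from tests.oracles import flood_fill_count


def _disk_mask(shape, centers, radius):
    m = np.zeros(shape, dtype=bool)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        m[rr, cc] = True
    return m


class TestCountComponents:
    def test_empty_mask(self):
        assert maskops.count_components(np.zeros((32, 32), bool)) == 0

    def test_three_disks_against_flood_fill(self):
        m = _disk_mask((64, 64), [(12, 12), (12, 45), (48, 30)], 10)
        assert maskops.count_components(m, min_area=20) == 3
        assert flood_fill_count(m, 20) == 3

    def test_small_component_filtered_by_area(self):
        m = _disk_mask((32, 32), [(16, 16)], 1.8)  # area ~ 10 px
        assert 0 < m.sum() < 20
        assert maskops.count_components(m, min_area=20) == 0
        assert maskops.count_components(m, min_area=0) == 1

    def test_matches_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.random((48, 48)) < rng.uniform(0.05, 0.5)
            for min_area in (0, 5, 25):
                assert maskops.count_components(m, min_area) == flood_fill_count(m, min_area)

    @given(st.integers(0, 2**31 - 1), st.integers(0, 60))
    @settings(max_examples=25, deadline=None)
    def test_count_monotone_nonincreasing_in_min_area(self, seed, a1):
        rng = np.random.default_rng(seed)
        m = rng.random((32, 32)) < 0.3
        a2 = a1 + int(rng.integers(1, 30))
        assert maskops.count_components(m, a2) <= maskops.count_components(m, a1)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError):
            maskops.count_components(np.zeros((4, 4), bool), -1)


class TestDenoiseMask:
    def test_empty_stays_empty(self):
        assert not maskops.denoise_mask(np.zeros((16, 16), bool), 1).any()

    def test_opening_removes_singletons_keeps_square(self):
        m = np.zeros((40, 40), bool)
        m[10:30, 10:30] = True
        singles = [(2, 2), (2, 37), (37, 2), (37, 37), (5, 20)]
        for r, c in singles:
            m[r, c] = True
        out = maskops.denoise_mask(m, 1)
        assert out[12:28, 12:28].all()
        for r, c in singles:
            assert not out[r, c]
        assert flood_fill_count(out) == 1

    def test_result_subset_of_dilated_input(self):
        rng = np.random.default_rng(3)
        m = rng.random((48, 48)) < 0.4
        out = maskops.denoise_mask(m, 2)
        from scipy.ndimage import binary_dilation
        assert not (out & ~binary_dilation(m, iterations=2)).any()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = rng.random((48, 48)) < 0.4
        once = maskops.denoise_mask(m, 1)
        assert np.array_equal(maskops.denoise_mask(once, 1), once)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            maskops.denoise_mask(np.zeros((4, 4), bool), -1)


def _library_from_counts(counts, shape=(96, 128), seed=0):
    cfg = synthdata.old_preset(shape[1], shape[0])
    entries = []
    for i, k in enumerate(counts):
        s = synthdata.generate_sample(cfg, k, rng_seed=seed + i)
        entries.append((s.mask, k))
    return maskops.MaskLibrary(entries=entries)


class TestCombineMasks:
    def test_two_plus_three_gives_five(self):
        lib = _library_from_counts([2, 3])
        out = maskops.combine_masks(lib, 5, rng_seed=1)
        assert flood_fill_count(out) == 5

    def test_single_mask_reused_with_translation(self):
        lib = _library_from_counts([1])
        out = maskops.combine_masks(lib, 2, rng_seed=2)
        assert flood_fill_count(out) == 2

    def test_unsatisfiable_target_raises(self):
        lib = _library_from_counts([3])
        with pytest.raises(maskops.MaskSynthesisError):
            maskops.combine_masks(lib, 4, rng_seed=0)

    def test_zero_target_gives_empty(self):
        lib = _library_from_counts([2])
        assert not maskops.combine_masks(lib, 0, rng_seed=0).any()

    def test_library_validates_recorded_counts(self):
        m = _disk_mask((32, 32), [(8, 8), (24, 24)], 4)
        with pytest.raises(ValueError, match="recorded count"):
            maskops.MaskLibrary(entries=[(m, 3)])


class TestCountFromSegmentation:
    def test_constant_zero_map(self):
        assert maskops.count_from_segmentation(np.zeros((32, 32)), 0.5, 1, 10) == 0

    def test_pipeline_identity_on_clean_mask(self):
        # resolution where storage roots are thick relative to the opening
        # element, as in real captures
        cfg = synthdata.old_preset(480, 360)
        s = synthdata.generate_sample(cfg, 4, rng_seed=9)
        assert maskops.count_from_segmentation(s.mask.astype(float), 0.5, 1, 30) == 4

    def test_composition_law(self):
        rng = np.random.default_rng(5)
        prob = rng.random((48, 48))
        direct = maskops.count_from_segmentation(prob, 0.6, 1, 12)
        staged = maskops.count_components(
            maskops.denoise_mask(prob >= 0.6, 1), 12)
        assert direct == staged

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            maskops.count_from_segmentation(np.zeros((8, 8)), 1.5)
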