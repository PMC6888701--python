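"""Manifest-backed data loading shared by the training routines.

Images are loaded once into memory (datasets at this package's scale are
small), resized with bilinear interpolation, kept in [0, 1], and arranged
NCHW for the networks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import io as rcio

AGE_TO_LABEL = {"old": 0, "young": 1}
LABEL_TO_AGE = {v: k for k, v in AGE_TO_LABEL.items()}


def to_nchw(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) float -> (N, 3, H, W) float32."""
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32)


def resize_image(img: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == tuple(hw):
        return img.astype(np.float32)
    return resize(img, hw, order=1, anti_aliasing=True, preserve_range=True).astype(np.float32)


def load_split(manifest: pd.DataFrame, split: str, hw: tuple[int, int],
               with_masks: bool = False):
    """Load one split's images (and optionally masks) at size ``hw`` (H, W).

    Returns (images NCHW, labels dataframe slice[, masks (N, H, W) bool]).
    """
    rows = manifest[manifest["split"] == split] if split else manifest
    imgs, masks = [], []
    for _, row in rows.iterrows():
        imgs.append(resize_image(rcio.read_image_png(row["path_image"]), hw))
        if with_masks:
            m = rcio.read_mask_png(row["path_mask"]).astype(np.float32)
            masks.append(resize_image(m, hw) > 0.5)
    imgs = to_nchw(np.stack(imgs)) if imgs else np.zeros((0, 3) + tuple(hw), np.float32)
    if with_masks:
        mk = np.stack(masks) if masks else np.zeros((0,) + tuple(hw), bool)
        return imgs, rows.reset_index(drop=True), mk
    return imgs, rows.reset_index(drop=True)


def iter_batches(n: int, batch_size: int, rng: np.random.Generator | None = None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
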