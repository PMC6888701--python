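"""File formats: 8-bit PNG images/masks and the CSV dataset manifest.

Conventions: images are float arrays in [0, 1], RGB, row-major with origin
top-left; masks are boolean arrays stored as 8-bit grayscale PNG with
values {0, 255} and binarized on read at > 127.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["sample_id", "path_image", "path_mask", "count", "age", "provenance", "split"]


def write_image_png(path: str, image: np.ndarray) -> None:
    """Write a float RGB image in [0, 1] as 8-bit PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def read_image_png(path: str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3].astype(np.float32) / 255.0


def write_mask_png(path: str, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_mask_png(path: str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "split"]
    if missing:
        raise ValueError(f"manifest at {path} lacks columns: {missing}")
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
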