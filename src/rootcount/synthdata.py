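"""Procedural generation of cassava-root-like images, masks and labels.

Real aeroponic capture produces RGB photographs of roots hung over a dark
background: a handful of thick, tapered storage roots descending from the
stem, tangled with many thin fibrous roots of similar colour.  This module
emulates that structure so the GAN, the classifiers and the segmentation
baseline can all be trained and evaluated without the (unreleased) field
data.  Storage roots are drawn as tapered quadratic Bezier strokes from a
shared anchor band at the top of the frame; fibrous roots are thin jittered
random-walk curves drawn both under and over them.  "Young" presets have
thinner, dimmer storage roots and heavier fibrous occlusion than "old"
presets, which is the property that makes young roots harder to count.

All randomness flows from explicit integer seeds; identical (config, count,
seed) triples produce bit-identical samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import disk as draw_disk

from . import io as rcio

__all__ = [
    "SynthConfig", "Sample", "young_preset", "old_preset",
    "generate_sample", "generate_dataset", "split_manifest",
]

REFERENCE_WIDTH = 960  # capture resolution the preset geometry is tuned at


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the procedural root-image generator.

    Widths are in pixels at the configured image size; presets scale them
    from the 960x720 capture geometry.
    """

    image_width: int = 960
    image_height: int = 720
    count_range: tuple[int, int] = (0, 6)
    age_class: str = "old"
    storage_width_range: tuple[float, float] = (18.0, 30.0)
    fibrous_count_range: tuple[int, int] = (15, 30)
    fibrous_width: float = 3.0
    curvature: float = 0.15
    occlusion_density: float = 0.10
    background_intensity: float = 0.06
    noise_sigma: float = 0.02
    storage_brightness: tuple[float, float] = (0.55, 0.78)
    fibrous_brightness: tuple[float, float] = (0.25, 0.45)
    min_separation: float = 2.0   # clearance between storage roots, pixels
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError(f"invalid count_range {self.count_range}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.age_class not in ("young", "old"):
            raise ValueError(f"age_class must be 'young' or 'old', got {self.age_class!r}")


@dataclass
class Sample:
    """One labeled observation: image, storage-root mask, count, age."""

    image: np.ndarray        # (H, W, 3) float in [0, 1]
    mask: np.ndarray         # (H, W) bool, True = storage-root pixel
    count: int
    age: str
    provenance: str = "procedural"


def _scaled(width: int, cfg_values: tuple[float, float]) -> tuple[float, float]:
    f = width / REFERENCE_WIDTH
    return (max(1.0, cfg_values[0] * f), max(1.5, cfg_values[1] * f))


def old_preset(image_width: int = 960, image_height: int = 720, **overrides) -> SynthConfig:
    """Roots at least 2.5 months old: thick, bright, well-separated storage
    roots with relatively light fibrous occlusion."""
    cfg = SynthConfig(
        image_width=image_width, image_height=image_height, age_class="old",
        storage_width_range=_scaled(image_width, (18.0, 30.0)),
        fibrous_width=max(1.0, 3.0 * image_width / REFERENCE_WIDTH),
        fibrous_count_range=(15, 30),
        occlusion_density=0.10,
        storage_brightness=(0.55, 0.78),
    )
    return replace(cfg, **overrides) if overrides else cfg


def young_preset(image_width: int = 960, image_height: int = 720, **overrides) -> SynthConfig:
    """Roots under 2.5 months: thinner, dimmer storage roots, heavier
    occlusion by fibrous roots of similar colour."""
    cfg = SynthConfig(
        image_width=image_width, image_height=image_height, age_class="young",
        storage_width_range=_scaled(image_width, (8.0, 14.0)),
        fibrous_width=max(1.0, 3.0 * image_width / REFERENCE_WIDTH),
        fibrous_count_range=(25, 45),
        occlusion_density=0.35,
        storage_brightness=(0.40, 0.58),
    )
    return replace(cfg, **overrides) if overrides else cfg


# ------------------------------------------------------------------ drawing

def _bezier_points(p0, p1, p2, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t ** 2) * p2


def _densify(pts, widths, step=0.6):
    """Resample a polyline (and per-point widths) to ~``step``-pixel spacing
    so disk stamps form a contiguous stroke."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < step:
        return pts, widths
    t = np.linspace(0.0, total, max(int(total / step) + 1, 2))
    rows = np.interp(t, arc, pts[:, 0])
    cols = np.interp(t, arc, pts[:, 1])
    ws = np.interp(t, arc, widths)
    return np.stack([rows, cols], axis=1), ws


def _draw_stroke(canvas_shape, pts, widths):
    """Rasterize a polyline of (row, col) points with per-point disk radii."""
    pts, widths = _densify(np.asarray(pts, float), np.asarray(widths, float))
    # clamp to the frame so a curve cannot exit and re-enter, which would
    # split one root into several components
    pts[:, 0] = np.clip(pts[:, 0], 0, canvas_shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, canvas_shape[1] - 1)
    layer = np.zeros(canvas_shape, dtype=bool)
    for (r, c), w in zip(pts, widths):
        rr, cc = draw_disk((r, c), max(w / 2.0, 0.85), shape=canvas_shape)
        layer[rr, cc] = True
    return layer


def _storage_root_layer(cfg: SynthConfig, rng: np.random.Generator, x_band=(0.15, 0.85)):
    h, w = cfg.image_height, cfg.image_width
    x0 = rng.uniform(x_band[0] * w, x_band[1] * w)
    y0 = rng.uniform(0.0, 0.06 * h)
    length = rng.uniform(0.55, 0.92) * h
    band_px = (x_band[1] - x_band[0]) * w
    drift = rng.normal(0.0, min(0.10 * w, 0.9 * band_px))
    x2 = np.clip(x0 + drift, x_band[0] * w, x_band[1] * w)
    y2 = min(y0 + length, 0.98 * h)
    jitter = rng.normal(0.0, min(cfg.curvature * w, 0.9 * band_px))
    p0 = np.array([y0, x0])
    p2 = np.array([y2, x2])
    p1 = (p0 + p2) / 2 + np.array([0.0, jitter])
    n = max(24, int(length / 2))
    pts = _bezier_points(p0, p1, p2, n)
    # curvature may not carry the stroke outside its anchor band
    pts[:, 1] = np.clip(pts[:, 1], x_band[0] * w, x_band[1] * w)
    base_w = rng.uniform(*cfg.storage_width_range)
    widths = np.linspace(base_w, max(1.5, 0.15 * base_w), n)  # taper toward tip
    return _draw_stroke((h, w), pts, widths)


def _fibrous_layer(cfg: SynthConfig, rng: np.random.Generator, through=None):
    h, w = cfg.image_height, cfg.image_width
    if through is None:
        x0 = rng.uniform(0.05 * w, 0.95 * w)
        y0 = rng.uniform(0.0, 0.08 * h)
    else:
        ty, tx = through
        x0 = np.clip(tx + rng.normal(0, 0.05 * w), 0, w - 1)
        y0 = max(0.0, ty - rng.uniform(0.2, 0.5) * h)
    n = rng.integers(30, 80)
    steps_y = rng.uniform(0.6, 1.4, n) * (0.9 * h / n)
    steps_x = rng.normal(0.0, 0.02 * w, n)
    rr = np.clip(y0 + np.cumsum(steps_y), 0, h - 1)
    cc = np.clip(x0 + np.cumsum(steps_x), 0, w - 1)
    pts = np.stack([rr, cc], axis=1)
    widths = np.full(n, cfg.fibrous_width)
    return _draw_stroke((h, w), pts, widths)


def generate_sample(config: SynthConfig, count: int, rng_seed: int) -> Sample:
    """Generate one procedural sample with exactly ``count`` storage roots.

    With the default non-overlap placement, storage roots are rejected and
    resampled until their (slightly dilated) footprints are pairwise
    disjoint, so the mask has exactly ``count`` 8-connected components.
    """
    lo, hi = config.count_range
    if not (lo <= count <= hi):
        raise ValueError(f"count {count} outside configured range [{lo}, {hi}]")
    rng = np.random.default_rng(rng_seed)
    h, w = config.image_height, config.image_width

    sep = max(1, int(round(config.min_separation / 2)))
    struct = np.ones((2 * sep + 1, 2 * sep + 1), dtype=bool)
    # anchor slots stratified across the width (permuted) keep multi-root
    # placement feasible in narrow frames; jitter stays within each slot,
    # shrunk so each root's full width plus clearance fits inside
    edges = np.linspace(0.12, 0.88, count + 1)
    margin = (config.storage_width_range[1] / 2 + config.min_separation) / w

    for restart in range(25):
        # dilated footprint of placed roots; a new root must avoid it,
        # keeping components 8-disconnected with min_separation clearance
        mask = np.zeros((h, w), dtype=bool)
        guard = np.zeros((h, w), dtype=bool)
        layers = []
        slot_order = rng.permutation(count) if count else []
        for slot in slot_order:
            lo, hi = edges[slot], edges[slot + 1]
            if hi - lo > 2.5 * margin:
                lo, hi = lo + margin, hi - margin
            for attempt in range(300):
                layer = _storage_root_layer(config, rng, x_band=(lo, hi))
                if config.allow_overlap or not (layer & guard).any():
                    mask |= layer
                    guard |= binary_dilation(layer, structure=struct)
                    layers.append(layer)
                    break
            else:
                break  # deadlocked placement: restart the whole sample
        if len(layers) == count:
            break
    else:
        raise RuntimeError(
            f"could not place {count} non-overlapping storage roots "
            f"in a {w}x{h} frame; widen the frame or allow overlap")

    image = np.full((h, w, 3), config.background_intensity, dtype=np.float32)

    def paint(layer, brightness, hue):
        color = np.array([brightness, brightness * hue[0], brightness * hue[1]], dtype=np.float32)
        image[layer] = color

    n_fib = int(rng.integers(config.fibrous_count_range[0], config.fibrous_count_range[1] + 1))
    under = [_fibrous_layer(config, rng) for _ in range(n_fib)]
    for lay in under:
        paint(lay, rng.uniform(*config.fibrous_brightness), (rng.uniform(0.7, 0.9), rng.uniform(0.4, 0.6)))

    for lay in layers:
        paint(lay, rng.uniform(*config.storage_brightness), (rng.uniform(0.75, 0.9), rng.uniform(0.5, 0.65)))

    # overdraw fibrous roots across storage roots until the requested
    # fraction of storage pixels is occluded (ground-truth mask unchanged)
    storage_px = int(mask.sum())
    if storage_px and config.occlusion_density > 0:
        covered = np.zeros((h, w), dtype=bool)
        ys, xs = np.nonzero(mask)
        for _ in range(200):
            if covered[mask].sum() >= config.occlusion_density * storage_px:
                break
            k = rng.integers(len(ys))
            lay = _fibrous_layer(config, rng, through=(ys[k], xs[k]))
            paint(lay, rng.uniform(*config.fibrous_brightness), (rng.uniform(0.7, 0.9), rng.uniform(0.4, 0.6)))
            covered |= lay

    image += rng.normal(0.0, config.noise_sigma, size=image.shape).astype(np.float32)
    np.clip(image, 0.0, 1.0, out=image)
    return Sample(image=image, mask=mask, count=count, age=config.age_class)


# ----------------------------------------------------------------- datasets

def generate_dataset(config_by_class: dict[str, SynthConfig],
                     n_per_count: dict[int, int],
                     rng_seed: int,
                     out_dir: str) -> pd.DataFrame:
    """Write a procedural dataset to ``out_dir`` and return its manifest.

    ``n_per_count[k] = 0`` deliberately creates a missing count class, the
    scenario the GAN augmentation workflow exists to repair.  One manifest
    row is produced per sample and age class; file bytes are deterministic
    given ``rng_seed``.
    """
    img_dir = rcio.ensure_dir(os.path.join(out_dir, "images"))
    msk_dir = rcio.ensure_dir(os.path.join(out_dir, "masks"))
    rows = []
    for ci, (age, cfg) in enumerate(sorted(config_by_class.items())):
        for count, n in sorted(n_per_count.items()):
            lo, hi = cfg.count_range
            if not (lo <= count <= hi):
                raise ValueError(f"requested count {count} outside {cfg.count_range}")
            for rep in range(n):
                seed = int(np.random.SeedSequence([rng_seed, ci, count, rep]).generate_state(1)[0] % (2**31))
                sample = generate_sample(cfg, count, seed)
                sid = f"{age}_c{count}_{rep:03d}"
                p_img = os.path.join(img_dir, sid + ".png")
                p_msk = os.path.join(msk_dir, sid + ".png")
                rcio.write_image_png(p_img, sample.image)
                rcio.write_mask_png(p_msk, sample.mask)
                rows.append({"sample_id": sid, "path_image": p_img, "path_mask": p_msk,
                             "count": count, "age": age, "provenance": "procedural",
                             "split": ""})
    return pd.DataFrame(rows, columns=rcio.MANIFEST_COLUMNS)


def split_manifest(manifest: pd.DataFrame, rng_seed: int) -> pd.DataFrame:
    """Assign train/val/test splits: 20% test, then 20% of the remainder as
    validation (16% of the total), rounding half up on each draw."""
    n = len(manifest)
    if n < 3:
        raise ValueError(f"need at least 3 rows to split, got {n}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    n_test = int(np.floor(0.2 * n + 0.5))
    n_val = int(np.floor(0.2 * (n - n_test) + 0.5))
    split = np.full(n, "train", dtype=object)
    split[order[:n_test]] = "test"
    split[order[n_test:n_test + n_val]] = "val"
    out = manifest.copy()
    out["split"] = split
    return out
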