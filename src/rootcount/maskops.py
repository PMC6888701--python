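"""Mask-level computation: conditioning-mask synthesis for missing count
classes, morphological denoising, and counting storage roots from a mask.

Counting treats a storage root as one 8-connected foreground component
(roots are diagonal-heavy curves, so 4-connectivity would split them);
components below a pixel-area floor are discarded as segmentation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "MaskLibrary", "combine_masks", "denoise_mask", "count_components",
    "count_from_segmentation", "MaskSynthesisError", "PlacementError",
]

EIGHT = np.ones((3, 3), dtype=bool)


class MaskSynthesisError(ValueError):
    """No combination of available mask counts sums to the target."""


class PlacementError(RuntimeError):
    """No zero-overlap translation found within the retry budget."""


@dataclass
class MaskLibrary:
    """Binary storage-root masks indexed by their root count."""

    entries: list = field(default_factory=list)   # list of (mask: bool array, count: int)
    min_area: int = 0

    def __post_init__(self):
        self.index: dict[int, list[int]] = {}
        for pos, (mask, count) in enumerate(self.entries):
            actual = count_components(np.asarray(mask, dtype=bool), self.min_area)
            if actual != count:
                raise ValueError(
                    f"library entry {pos} recorded count {count} but mask has "
                    f"{actual} components at min_area={self.min_area}")
            self.index.setdefault(int(count), []).append(pos)

    def add(self, mask, count):
        self.entries.append((np.asarray(mask, dtype=bool), int(count)))
        self.__post_init__()

    @property
    def counts(self):
        return sorted(self.index)

    @classmethod
    def from_manifest(cls, manifest, read_mask, min_area: int = 0, max_per_count: int | None = None):
        """Build a library from manifest rows whose mask component count
        matches the recorded label (others are skipped, not errors)."""
        entries, per_count = [], {}
        for _, row in manifest.iterrows():
            if row["count"] <= 0:
                continue
            if max_per_count is not None and per_count.get(row["count"], 0) >= max_per_count:
                continue
            mask = read_mask(row["path_mask"])
            if count_components(mask, min_area) == row["count"]:
                entries.append((mask, int(row["count"])))
                per_count[row["count"]] = per_count.get(row["count"], 0) + 1
        return cls(entries=entries, min_area=min_area)


def _subset_summing(counts_available: list[int], target: int, rng: np.random.Generator,
                    max_parts: int = 6):
    """Pick a multiset of available counts summing to target (greedy with
    randomized order, falling back to exhaustive small search)."""
    avail = sorted(set(counts_available), reverse=True)
    # depth-first search over counts with repetition, randomized tie-break
    stack = [(target, [])]
    best = None
    while stack:
        remaining, chosen = stack.pop()
        if remaining == 0 and chosen:
            best = chosen
            break
        if len(chosen) >= max_parts:
            continue
        opts = [c for c in avail if c <= remaining]
        rng.shuffle(opts)
        for c in opts:
            stack.append((remaining - c, chosen + [c]))
    return best


def combine_masks(library: MaskLibrary, target_count: int, rng_seed: int,
                  max_tries: int = 200) -> np.ndarray:
    """Union masks from the library into one with ``target_count`` roots.

    Later masks are translated horizontally by rejection-sampled offsets
    until their foreground (with a 1-pixel guard band, so components stay
    8-disconnected) does not touch what is already placed.  Horizontal-only
    translation preserves the hanging-root geometry of the source masks.
    """
    if target_count == 0:
        if not library.entries:
            raise MaskSynthesisError("empty library")
        h, w = library.entries[0][0].shape
        return np.zeros((h, w), dtype=bool)
    rng = np.random.default_rng(rng_seed)
    parts = _subset_summing(library.counts, target_count, rng)
    if parts is None:
        raise MaskSynthesisError(
            f"no combination of available counts {library.counts} sums to {target_count}")
    shapes = {library.entries[0][0].shape}
    for m, _ in library.entries:
        shapes.add(m.shape)
    if len(shapes) != 1:
        raise ValueError("all library masks must share dimensions")
    h, w = shapes.pop()

    out = np.zeros((h, w), dtype=bool)
    guard = np.zeros((h, w), dtype=bool)
    for k, part in enumerate(parts):
        pos = int(rng.choice(library.index[part]))
        mask = library.entries[pos][0]
        placed = False
        for _ in range(max_tries):
            dx = 0 if k == 0 else int(rng.integers(-w // 2, w // 2 + 1))
            shifted = _hshift(mask, dx)
            if count_components(shifted, library.min_area) != part:
                continue  # translation clipped a root off-frame
            if not (shifted & guard).any():
                out |= shifted
                guard |= ndimage.binary_dilation(shifted, structure=EIGHT)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"no zero-overlap horizontal placement found for a {part}-root "
                f"mask within {max_tries} tries")
    return out


def _hshift(mask: np.ndarray, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    if dx == 0:
        return mask.copy()
    if dx > 0:
        out[:, dx:] = mask[:, :-dx]
    else:
        out[:, :dx] = mask[:, -dx:]
    return out


def denoise_mask(mask: np.ndarray, opening_radius: int) -> np.ndarray:
    """Morphological opening with a disk element: erodes away speckle
    smaller than the disk, then restores the surviving shapes."""
    if opening_radius < 0:
        raise ValueError(f"opening_radius must be >= 0, got {opening_radius}")
    mask = np.asarray(mask, dtype=bool)
    if opening_radius == 0:
        return mask.copy()
    return ndimage.binary_opening(mask, structure=disk(opening_radius).astype(bool))


def count_components(mask: np.ndarray, min_area: int = 0) -> int:
    """Number of 8-connected foreground components with area >= min_area."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=EIGHT)
    if n == 0 or min_area <= 1:
        return int(n)
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area).sum())


def count_from_segmentation(prob_map: np.ndarray, threshold: float = 0.5,
                            opening_radius: int = 1, min_area: int = 50) -> int:
    """Counting pipeline of the segmentation baseline: threshold the
    per-pixel storage-root probabilities, denoise, count components."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob_map = np.asarray(prob_map)
    if prob_map.min() < -1e-6 or prob_map.max() > 1 + 1e-6:
        raise ValueError("probability map values must lie in [0, 1]")
    binary = prob_map >= threshold
    return count_components(denoise_mask(binary, opening_radius), min_area)
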