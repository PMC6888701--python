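"""Independent reference implementations used only by tests.

These deliberately avoid the library code paths they check: component
counting by explicit flood fill, and segmentation scores computed directly
from per-pixel label comparisons rather than from a confusion matrix.
"""

from collections import deque

import numpy as np


def flood_fill_count(mask, min_area=0):
    """Count 8-connected foreground components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for sr in range(h):
        for sc in range(w):
            if mask[sr, sc] and not seen[sr, sc]:
                area = 0
                q = deque([(sr, sc)])
                seen[sr, sc] = True
                while q:
                    r, c = q.popleft()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                if area >= min_area:
                    count += 1
    return count


def brute_force_seg_scores(gt, pred, c):
    """Pixel accuracy, mean IoU, average precision/recall straight from the
    label rasters (absent-on-both-sides classes score 1, one-sided score 0)."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    pixel_acc = float(np.mean(gt == pred)) if gt.size else float("nan")
    ious, precs, recs = [], [], []
    for i in range(c):
        g = gt == i
        p = pred == i
        inter = float(np.sum(g & p))
        union = float(np.sum(g | p))
        ious.append(inter / union if union else 1.0)
        n_p, n_g = float(p.sum()), float(g.sum())
        precs.append(inter / n_p if n_p else (1.0 if n_g == 0 else 0.0))
        recs.append(inter / n_g if n_g else (1.0 if n_p == 0 else 0.0))
    return pixel_acc, float(np.mean(ious)), float(np.mean(precs)), float(np.mean(recs))
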