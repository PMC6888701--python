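"""Two-stage inference and end-to-end evaluation.

Counting proceeds in two stages: an age classifier first labels the image
"old" or "young", and that label selects which of two identically-shaped
count classifiers produces the storage-root count.  The same test images
can also be counted by the segmentation baseline (segment, denoise, count
components), and :func:`evaluate_system` scores both routes with the
counting metrics plus the segmenter's pixel-level scores.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify_models, data as rcdata, gan as rcgan, maskops, metrics, segment_models
from . import io as rcio
from .modelspec import TrainedModel

log = logging.getLogger(__name__)

__all__ = ["TwoStageSystem", "two_stage_count", "augment_missing_classes", "evaluate_system"]


@dataclass
class TwoStageSystem:
    """Age model (2-way) routing between two count models of equal arity."""

    age_model: TrainedModel
    count_model_old: TrainedModel
    count_model_young: TrainedModel

    def __post_init__(self):
        if self.age_model.spec.output_arity != 2:
            raise ValueError("age model must have arity 2")
        if self.count_model_old.spec.output_arity != self.count_model_young.spec.output_arity:
            raise ValueError("count models must share output arity")


def two_stage_count(system: TwoStageSystem, image: np.ndarray):
    """Predict (age, count) for one HWC image: the age model's argmax picks
    exactly one count model, whose argmax is the count."""
    age_label, _ = classify_models.predict_class(system.age_model, image)
    age = rcdata.LABEL_TO_AGE[age_label]
    counter = system.count_model_old if age == "old" else system.count_model_young
    count, _ = classify_models.predict_class(counter, image)
    return age, count


def augment_missing_classes(manifest: pd.DataFrame, gen: TrainedModel,
                            count_range: tuple[int, int], min_per_class: int = 10,
                            seed: int = 0, out_dir: str | None = None,
                            age: str = "old") -> pd.DataFrame:
    """Fill count classes that have no training rows with GAN samples.

    The mask library is built from the manifest's train rows; synthetic rows
    are confined to the train split.  Classes whose target count cannot be
    assembled from available masks are reported and skipped.
    """
    train = manifest[manifest["split"] == "train"]
    missing = [k for k in range(count_range[0], count_range[1] + 1)
               if (train["count"] == k).sum() == 0 and k > 0]
    if not missing:
        return manifest
    library = maskops.MaskLibrary.from_manifest(train, rcio.read_mask_png)
    new_rows = []
    for k in missing:
        try:
            samples = rcgan.generate_for_missing_class(gen, library, k, min_per_class,
                                                       seed=seed + k, age=age)
        except maskops.MaskSynthesisError as exc:
            log.warning("count class %d cannot be synthesized: %s", k, exc)
            continue
        for i, s in enumerate(samples):
            sid = f"gan_{age}_c{k}_{i:03d}"
            if out_dir is not None:
                rcio.ensure_dir(os.path.join(out_dir, "images"))
                rcio.ensure_dir(os.path.join(out_dir, "masks"))
                p_img = os.path.join(out_dir, "images", sid + ".png")
                p_msk = os.path.join(out_dir, "masks", sid + ".png")
                rcio.write_image_png(p_img, s.image)
                rcio.write_mask_png(p_msk, s.mask)
            else:
                p_img = p_msk = ""
            new_rows.append({"sample_id": sid, "path_image": p_img, "path_mask": p_msk,
                             "count": k, "age": age, "provenance": "gan", "split": "train"})
    return pd.concat([manifest, pd.DataFrame(new_rows, columns=rcio.MANIFEST_COLUMNS)],
                     ignore_index=True)


def evaluate_system(system: TwoStageSystem, manifest: pd.DataFrame,
                    seg_model: TrainedModel | None = None,
                    seg_threshold: float = 0.5, opening_radius: int = 1,
                    min_area: int = 50, out_dir: str | None = None) -> dict:
    """Score the two-stage CNN counts (and optionally the segmentation
    baseline) on the manifest's test split.

    Returns a report dict with per-age-class CountScores for each route,
    age-prediction accuracy, SegScores of the segmenter, and the per-sample
    table from which every aggregate is recomputable.
    """
    test = manifest[manifest["split"] == "test"]
    if len(test) == 0:
        raise ValueError("test split is empty")
    per_sample = []
    cm_total = None
    for _, row in test.iterrows():
        image = rcio.read_image_png(row["path_image"])
        age_pred, count_cnn = two_stage_count(system, image)
        rec = {"sample_id": row["sample_id"], "gt": int(row["count"]),
               "age_gt": row["age"], "age_pred": age_pred, "pred_cnn": count_cnn}
        if seg_model is not None:
            prob = segment_models.segment(seg_model, image)
            rec["pred_seg"] = maskops.count_from_segmentation(
                prob, seg_threshold, opening_radius, min_area)
            if row["path_mask"]:
                hw = seg_model.spec.input_size
                gt_mask = rcdata.resize_image(
                    rcio.read_mask_png(row["path_mask"]).astype(np.float32), hw) > 0.5
                cm = metrics.confusion(gt_mask.astype(int), (prob >= seg_threshold).astype(int), 2)
                cm_total = cm if cm_total is None else cm_total + cm
        per_sample.append(rec)
    table = pd.DataFrame(per_sample)

    report = {"n_test": len(table),
              "age_accuracy": float((table["age_gt"] == table["age_pred"]).mean()),
              "count_scores": {}}
    for route in ["pred_cnn"] + (["pred_seg"] if seg_model is not None else []):
        name = "cnn" if route == "pred_cnn" else "seg"
        report["count_scores"][name] = {}
        for age, sub in [("all", table)] + list(table.groupby("age_gt")):
            report["count_scores"][name][age] = metrics.count_scores(
                sub[route].to_numpy(), sub["gt"].to_numpy()).as_dict()
    if cm_total is not None:
        report["seg_scores"] = metrics.seg_scores(cm_total).as_dict()
    if out_dir is not None:
        rcio.ensure_dir(out_dir)
        table.to_csv(os.path.join(out_dir, "per_sample.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1)
    return report
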