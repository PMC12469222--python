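"""End-to-end orchestration: detect -> crop -> train -> predict -> vCDR -> report.

The pipeline mirrors a clinical screening flow: locate the optic disc on
the full fundus frame, cut a square region of interest with a safety
margin, segment disc and cup inside it, smooth the masks by ellipse
refitting, measure the vertical cup-to-disc ratio and classify with the
0.5 rule.  Every stage reads and writes plain files, records its
thresholds and seeds in a log, and is deterministic under the configured
seeds, so a rerun reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage import transform as sktransform

from . import detection, metrics, unet, vcdr
from .synthetic import load_sample

#: Split presets used at the two pipeline stages.
DETECTION_SPLIT = (0.50, 0.25, 0.25)
SEGMENTATION_SPLIT = (0.60, 0.20, 0.20)

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class PipelineConfig:
    dataset_dir: str = "dataset"
    out_dir: str = "pipeline_out"
    detector: str = "bright_standin"  # or "from_file"
    boxes_dir: str | None = None  # YOLO txt per image when detector=from_file
    detect_size: int = 640
    margin: int = 70
    conf_thresh: float = 0.5
    nms_iou: float = 0.3
    preset: str = "small"
    input_size: int = 224
    epochs: int = 100
    batch_size: int = 2
    learning_rate: float = 5e-5
    vcdr_threshold: float = 0.5
    refit: bool = True
    split_fractions: tuple[float, float, float] = SEGMENTATION_SPLIT
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        for name in ("conf_thresh", "nms_iou", "vcdr_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.detector not in ("bright_standin", "from_file"):
            raise ValueError(f"unknown detector {self.detector!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = dataclasses.asdict(self)
        data["split_fractions"] = list(data["split_fractions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def split_dataset(manifest: pd.DataFrame,
                  fractions: tuple[float, float, float] = SEGMENTATION_SPLIT,
                  rng_seed: int = 0,
                  label_col: str = "label") -> pd.DataFrame:
    """Assign a stratified train/val/test split column.

    Within each class the samples are shuffled deterministically and
    allocated so each split's class count is within one sample of the
    target fraction (floors first, remainders to the largest fractional
    parts).  Raises if any class has fewer samples than there are splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    out = manifest.copy()
    out["split"] = ""
    rng = np.random.default_rng(rng_seed)
    for label, group in out.groupby(label_col, sort=True):
        n = len(group)
        if n < len(fractions):
            raise ValueError(
                f"class {label!r} has {n} samples, fewer than the "
                f"{len(fractions)} splits")
        counts = [math.floor(f * n) for f in fractions]
        remainders = [f * n - c for f, c in zip(fractions, counts)]
        for _ in range(n - sum(counts)):
            k = int(np.argmax(remainders))
            counts[k] += 1
            remainders[k] = -1.0
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=object)
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            assignment[order[start : start + c]] = name
            start += c
        out.loc[group.index, "split"] = assignment
    return out


def _float_fmt(x: float) -> str:
    return "nan" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.6f}"


def _resize_to(image: np.ndarray, size: int, order: int) -> np.ndarray:
    if image.shape[:2] == (size, size):
        return image
    resized = sktransform.resize(image.astype(float), (size, size), order=order,
                                 preserve_range=True, anti_aliasing=False)
    return np.clip(resized, 0, 255).astype(np.uint8)


def run_pipeline(config: PipelineConfig):
    """Run every stage end-to-end over a generated dataset directory.

    Expects ``dataset_dir`` to hold ``images/``, ``masks/`` and
    ``manifest.csv`` (the synthetic generator's layout).  Writes the
    cropped dataset, the trained model, raw and ellipse-refit predicted
    masks, a per-image vCDR table and an evaluation report under
    ``out_dir``; returns the :class:`~fundus_vcdr.metrics.EvalReport`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed}", f"detector={config.detector}",
                 f"conf_thresh={config.conf_thresh}", f"nms_iou={config.nms_iou}",
                 f"margin={config.margin}", f"detect_size={config.detect_size}",
                 f"input_size={config.input_size}", f"preset={config.preset}",
                 f"epochs={config.epochs}", f"batch_size={config.batch_size}",
                 f"learning_rate={config.learning_rate}",
                 f"vcdr_threshold={config.vcdr_threshold}"]

    manifest = pd.read_csv(Path(config.dataset_dir) / "manifest.csv")

    # --- stage 1+2: detection and square ROI cropping -------------------
    crop_dir = out / "cropped"
    (crop_dir / "images").mkdir(parents=True, exist_ok=True)
    (crop_dir / "masks").mkdir(parents=True, exist_ok=True)
    kept_rows = []
    from .annotations import read_yolo_txt

    for row in manifest.itertuples():
        sample = load_sample(config.dataset_dir, row.filename)
        image = _resize_to(sample.image, config.detect_size, order=1)
        mask = _resize_to(sample.mask, config.detect_size, order=0)
        if config.detector == "from_file":
            txt = Path(config.boxes_dir) / (Path(row.filename).stem + ".txt")
            boxes = read_yolo_txt(txt, (config.detect_size, config.detect_size))
            boxes = detection.nms_filter(boxes, config.conf_thresh, config.nms_iou)
        else:
            boxes = detection.detect_od_bright(
                image, conf_thresh=config.conf_thresh, iou_thresh=config.nms_iou)
        if not boxes:
            log_lines.append(f"degenerate detect {row.filename}: no disc found")
            continue
        img_crop, mask_crop, record = detection.crop_square_roi(
            image, mask, boxes[0], margin=config.margin)
        iio.imwrite(crop_dir / "images" / row.filename, img_crop)
        iio.imwrite(crop_dir / "masks" / row.filename, mask_crop)
        kept_rows.append({
            "filename": row.filename, "split": "", "label": row.label,
            "true_vcdr": row.true_vcdr, "crop_side": record.side,
        })
    crop_manifest = pd.DataFrame(kept_rows)
    if crop_manifest.empty:
        raise RuntimeError("detection stage found no optic disc in any image")

    # --- stage 3: split + training --------------------------------------
    crop_manifest = split_dataset(crop_manifest, config.split_fractions,
                                  rng_seed=config.seed)
    crop_manifest.to_csv(crop_dir / "manifest.csv", index=False,
                         float_format="%.6f")
    train_rows = crop_manifest[crop_manifest["split"] == "train"]
    model = unet.build_model(unet.SegModelConfig(
        preset=config.preset, input_size=config.input_size,
        rng_seed=config.seed))
    train_samples = [load_sample(crop_dir, f) for f in train_rows["filename"]]
    trace = unet.train_model(model, train_samples, unet.TrainConfig(
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, rng_seed=config.seed))
    model.save(out / "model.npz")
    pd.DataFrame({"epoch": range(1, len(trace) + 1), "loss": trace}).to_csv(
        out / "training_curve.csv", index=False, float_format="%.6f")

    # --- stage 4: prediction + vCDR on the test split -------------------
    pred_dir = out / "predictions"
    (pred_dir / "raw").mkdir(parents=True, exist_ok=True)
    (pred_dir / "refit").mkdir(parents=True, exist_ok=True)
    test_rows = crop_manifest[crop_manifest["split"] == "test"]
    pred_masks, true_masks, true_vcdrs, names = [], [], [], []
    vcdr_records = []
    for row in test_rows.itertuples():
        sample = load_sample(crop_dir, row.filename)
        pred = unet.predict_labelmap(model, sample.image)
        iio.imwrite(pred_dir / "raw" / row.filename, pred)
        refit = vcdr.refit_mask_ellipses(pred)
        iio.imwrite(pred_dir / "refit" / row.filename, refit.mask)
        eval_mask = refit.mask if config.refit else pred
        rec = {"filename": row.filename}
        try:
            raw_res = vcdr.compute_vcdr(pred, config.vcdr_threshold)
            raw_vcdr = raw_res.vcdr
        except vcdr.MissingDiscError:
            raw_vcdr = math.nan
        try:
            res = vcdr.compute_vcdr(eval_mask, config.vcdr_threshold)
            rec.update(disc_vdiam=res.disc_vdiam, cup_vdiam=res.cup_vdiam,
                       vcdr_raw=_float_fmt(raw_vcdr),
                       vcdr_refit=_float_fmt(res.vcdr),
                       label=res.label, degenerate_flag=res.degenerate)
        except vcdr.MissingDiscError:
            log_lines.append(f"degenerate vcdr {row.filename}: no disc in prediction")
            rec.update(disc_vdiam=0, cup_vdiam=0, vcdr_raw=_float_fmt(raw_vcdr),
                       vcdr_refit="nan", label="normal", degenerate_flag=True)
        vcdr_records.append(rec)
        pred_masks.append(pred)
        true_masks.append(sample.mask)
        true_vcdrs.append(float(row.true_vcdr))
        names.append(row.filename)
    pd.DataFrame(vcdr_records).to_csv(out / "vcdr.csv", index=False)

    # --- stage 5: evaluation --------------------------------------------
    report = metrics.evaluate_segmentation_set(
        pred_masks, true_masks, true_vcdrs, refit=config.refit,
        vcdr_threshold=config.vcdr_threshold, names=names)
    report_df = pd.DataFrame([{
        "iou_od": report.iou_od, "iou_oc": report.iou_oc,
        "dsc_od": report.dsc_od, "dsc_oc": report.dsc_oc,
        "mean_iou": report.mean_iou,
        "mean_vcdr_error": report.mean_vcdr_error,
        "accuracy": report.classification.accuracy,
        "precision": report.classification.precision,
        "recall": report.classification.recall,
        "f1": report.classification.f1,
        "n_images": report.n_images,
        "n_degenerate": report.n_degenerate,
    }])
    report_df.to_csv(out / "report.csv", index=False, float_format="%.6f")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return report
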