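"""Bounding-box annotation I/O: YOLO-style txt and COCO-style JSON.

YOLO txt: one file per image, one line per box — ``class_id cx cy w h``
with center/size normalized to [0, 1] by the image dimensions.

COCO JSON: one file per dataset with ``images``, ``annotations`` and
``categories`` arrays; each annotation's ``bbox`` is ``[x, y, width,
height]`` in absolute pixels.

Both map losslessly (within 1e-6 after normalization) onto the package's
half-open :class:`~fundus_vcdr.detection.BBox` convention.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

from .detection import BBox


def write_yolo_txt(path: str | os.PathLike, boxes: list[BBox],
                   image_size: tuple[int, int]) -> None:
    """Write boxes normalized by ``image_size`` = (width, height)."""
    w, h = image_size
    lines = []
    for b in boxes:
        cx, cy = b.center
        lines.append(
            f"{b.class_id} {cx / w:.6f} {cy / h:.6f} "
            f"{b.width / w:.6f} {b.height / h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path: str | os.PathLike,
                  image_size: tuple[int, int]) -> list[BBox]:
    """Parse a YOLO annotation file into absolute-pixel boxes.

    Raises ValueError naming the offending line number on malformed input.
    """
    w, h = image_size
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            class_id = int(parts[0])
            cx, cy, bw, bh = (float(p) for p in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        boxes.append(BBox(
            x_min=(cx - bw / 2) * w, y_min=(cy - bh / 2) * h,
            x_max=(cx + bw / 2) * w, y_max=(cy + bh / 2) * h,
            confidence=conf, class_id=class_id))
    return boxes


def bbox_to_coco(box: BBox) -> list[float]:
    """Half-open BBox -> COCO [x, y, width, height]."""
    return [box.x_min, box.y_min, box.width, box.height]


def coco_to_bbox(xywh: list[float], confidence: float = 1.0,
                 class_id: int = 0) -> BBox:
    x, y, w, h = xywh
    return BBox(x, y, x + w, y + h, confidence=confidence, class_id=class_id)


def write_coco_json(path: str | os.PathLike,
                    annotations: dict[str, list[BBox]],
                    image_sizes: dict[str, tuple[int, int]]) -> None:
    """``annotations`` maps file name -> boxes; sizes are (width, height)."""
    images, anns = [], []
    ann_id = 1
    for img_id, (fname, boxes) in enumerate(sorted(annotations.items()), start=1):
        w, h = image_sizes[fname]
        images.append({"id": img_id, "file_name": fname, "width": w, "height": h})
        for b in boxes:
            anns.append({
                "id": ann_id, "image_id": img_id,
                "category_id": b.class_id,
                "bbox": bbox_to_coco(b),
                "score": b.confidence,
                "area": b.area, "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": anns,
        "categories": [{"id": 0, "name": "optic_disc"}],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_json(path: str | os.PathLike) -> dict[str, list[BBox]]:
    """Parse COCO JSON into a file-name -> boxes mapping.

    Raises ValueError if an annotation references a missing image id.
    """
    doc = json.loads(Path(path).read_text())
    by_id = {img["id"]: img["file_name"] for img in doc.get("images", [])}
    out: dict[str, list[BBox]] = {fname: [] for fname in by_id.values()}
    for ann in doc.get("annotations", []):
        img_id = ann["image_id"]
        if img_id not in by_id:
            raise ValueError(f"annotation {ann.get('id')} references "
                             f"missing image id {img_id}")
        out[by_id[img_id]].append(coco_to_bbox(
            ann["bbox"], confidence=ann.get("score", 1.0),
            class_id=ann.get("category_id", 0)))
    return out
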