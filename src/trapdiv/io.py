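"""Readers/writers for detection and table interchange formats.

Two detection dialects are supported:

* COCO-JSON — a single JSON document with ``images``, ``annotations`` and
  ``categories``; boxes as ``[x, y, w, h]`` in absolute pixels.  Detections
  carry ``score``, ``fold_id`` and ``side``; this is the canonical on-disk
  form.
* YOLO-txt — one text file per image side, lines of
  ``class cx cy w h [confidence]`` with center coordinates normalized by the
  image size; fold subdirectories ``fold_1 .. fold_k`` plus a
  ``classes.txt`` listing class names by index.

Tabular data (trap tables, count matrices, image->trap maps) are plain CSV
via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .boxes import Box
from .detect import Detection, GroundTruth

__all__ = [
    "write_coco",
    "read_coco",
    "write_yolo",
    "read_yolo",
    "read_counts",
    "write_counts",
    "read_traps",
]


def _coco_doc(
    records: Sequence[Detection | GroundTruth],
    image_size: tuple[int, int],
    image_ids: Sequence[str] | None = None,
) -> dict:
    names = sorted({r.class_label for r in records})
    cat_index = {n: i + 1 for i, n in enumerate(names)}
    imgs = list(image_ids) if image_ids is not None else sorted({r.image_id for r in records})
    img_index = {im: i + 1 for i, im in enumerate(imgs)}
    annotations = []
    for k, r in enumerate(records):
        ann = {
            "id": k + 1,
            "image_id": img_index[r.image_id],
            "category_id": cat_index[r.class_label],
            "bbox": [r.box.x_min, r.box.y_min, r.box.width, r.box.height],
            "area": r.box.area,
            "iscrowd": 0,
            "side": r.side,
        }
        if isinstance(r, Detection):
            ann["score"] = r.confidence
            ann["fold_id"] = r.fold_id
        else:
            ann["truth_id"] = r.truth_id
        annotations.append(ann)
    return {
        "images": [
            {"id": img_index[im], "file_name": f"{im}.jpg",
             "width": image_size[0], "height": image_size[1]}
            for im in imgs
        ],
        "annotations": annotations,
        "categories": [{"id": cat_index[n], "name": n} for n in names],
    }


def write_coco(
    records: Sequence[Detection | GroundTruth],
    path: str | Path,
    image_size: tuple[int, int],
    image_ids: Sequence[str] | None = None,
) -> None:
    """Write detections or ground truths as a COCO-JSON document."""
    with open(path, "w") as fh:
        json.dump(_coco_doc(records, image_size, image_ids), fh, indent=1)


def read_coco(path: str | Path) -> list[Detection] | list[GroundTruth]:
    """Read a COCO-JSON document written by :func:`write_coco`.

    Annotations with a ``score`` are detections; others are ground truths.
    """
    with open(path) as fh:
        doc = json.load(fh)
    cats = {c["id"]: c["name"] for c in doc["categories"]}
    imgs = {im["id"]: im["file_name"].rsplit(".", 1)[0] for im in doc["images"]}
    out: list = []
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        image_id = imgs[ann["image_id"]]
        side = ann.get("side", image_id.rsplit("_", 1)[-1])
        if "score" in ann:
            out.append(
                Detection(image_id, side, int(ann.get("fold_id", 1)),
                          cats[ann["category_id"]], Box(x, y, w, h), float(ann["score"]))
            )
        else:
            out.append(
                GroundTruth(image_id, side, cats[ann["category_id"]],
                            Box(x, y, w, h), int(ann.get("truth_id", -1)))
            )
    return out


def write_yolo(
    records: Sequence[Detection | GroundTruth],
    directory: str | Path,
    image_size: tuple[int, int],
    classes: Sequence[str] | None = None,
) -> None:
    """Write records as YOLO-txt files (one per image side).

    Detections go into ``fold_<i>/`` subdirectories and carry a sixth
    confidence column; truths go into ``truth/``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if classes is None:
        classes = sorted({r.class_label for r in records})
    idx = {n: i for i, n in enumerate(classes)}
    (directory / "classes.txt").write_text("\n".join(classes) + "\n")
    w_img, h_img = image_size
    lines: dict[Path, list[str]] = {}
    for r in records:
        cx = (r.box.x_min + r.box.width / 2) / w_img
        cy = (r.box.y_min + r.box.height / 2) / h_img
        bw, bh = r.box.width / w_img, r.box.height / h_img
        if isinstance(r, Detection):
            sub = directory / f"fold_{r.fold_id}"
            line = f"{idx[r.class_label]} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f} {r.confidence:.6f}"
        else:
            sub = directory / "truth"
            line = f"{idx[r.class_label]} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}"
        lines.setdefault(sub / f"{r.image_id}.txt", []).append(line)
    for path, ls in lines.items():
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(ls) + "\n")


def read_yolo(
    directory: str | Path,
    image_size: tuple[int, int],
    classes: Sequence[str] | None = None,
) -> tuple[list[Detection], list[GroundTruth]]:
    """Read YOLO-txt records written by :func:`write_yolo`."""
    directory = Path(directory)
    if classes is None:
        classes = (directory / "classes.txt").read_text().split()
    w_img, h_img = image_size
    dets: list[Detection] = []
    truths: list[GroundTruth] = []
    tid = 0

    def parse(path: Path, fold: int | None):
        nonlocal tid
        image_id = path.stem
        side = image_id.rsplit("_", 1)[-1]
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            ci = int(parts[0])
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
            box = Box((cx - bw / 2) * w_img, (cy - bh / 2) * h_img, bw * w_img, bh * h_img)
            if fold is None:
                truths.append(GroundTruth(image_id, side, classes[ci], box, tid))
                tid += 1
            else:
                conf = float(parts[5]) if len(parts) > 5 else 1.0
                dets.append(Detection(image_id, side, fold, classes[ci], box, conf))

    truth_dir = directory / "truth"
    if truth_dir.is_dir():
        for path in sorted(truth_dir.glob("*.txt")):
            parse(path, None)
    for fold_dir in sorted(directory.glob("fold_*")):
        fold = int(fold_dir.name.split("_")[1])
        for path in sorted(fold_dir.glob("*.txt")):
            parse(path, fold)
    return dets, truths


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label="trap_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="trap_id")


def read_traps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"trap_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"trap table missing columns: {sorted(missing)}")
    return df
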