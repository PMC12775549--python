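"""Detection post-processing: fold merging, threshold calibration, trait tables.

An object-detection ensemble trained by k-fold cross-validation produces, for
every trap-side photograph, five sets of candidate boxes with confidence
scores.  This module turns those raw candidates into a biological data table
in four steps:

1. per-class, per-fold confidence-threshold calibration against held-out
   annotations (precision/recall/F1 sweep over a threshold grid);
2. exclusion of unreliable classes (non-insect, sparsely annotated, or
   calibrated to a zero threshold);
3. cross-fold deduplication by greedy non-maximum suppression on IoU;
4. aggregation into per-trap abundance and body-size (max bounding-box area)
   tables.

Deduplication is class-agnostic (folds may disagree on the class of one
insect; the highest-confidence call wins), while precision/recall matching is
class-specific, as is standard in detection evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boxes import Box, iou

__all__ = [
    "Detection",
    "GroundTruth",
    "PerformanceCurve",
    "ClassCalibration",
    "MatchResult",
    "merge_folds",
    "match_to_truth",
    "sweep_thresholds",
    "select_threshold",
    "calibrate",
    "apply_exclusions",
    "assign_lifecycle",
    "apply_thresholds",
    "build_trait_table",
    "mean_average_precision",
    "DEFAULT_LIFECYCLES",
    "AQUATIC_TAXA",
    "TERRESTRIAL_TAXA",
]


@dataclass(frozen=True)
class Detection:
    """One inferred bounding box from one cross-validation fold."""

    image_id: str
    side: str  # "A" or "B"
    fold_id: int
    class_label: str
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """One annotated (truth) bounding box."""

    image_id: str
    side: str
    class_label: str
    box: Box
    truth_id: int = -1


@dataclass
class PerformanceCurve:
    """Precision/recall/F1 as a function of the confidence threshold.

    Undefined cells (zero denominator) are NaN and are never eligible as
    maxima during threshold selection.
    """

    class_label: str
    fold_id: int
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    n_truth: int


@dataclass
class ClassCalibration:
    """Per-class calibration outcome across folds."""

    class_label: str
    fold_thresholds: dict[int, float]
    n_training_annotations: int = 0
    is_insect: bool = True
    retained: bool = True
    exclusion_reason: str = "none"  # none | non_insect | under_30_training | threshold_zero


@dataclass
class MatchResult:
    """TP/FP labelling of detections plus the count of unmatched truths."""

    detections: list[Detection]
    is_tp: list[bool]
    n_truth: int

    @property
    def n_fn(self) -> int:
        return self.n_truth - sum(self.is_tp)


def _sort_key(d: Detection):
    # descending confidence; ties by fold then class then geometry so the
    # merge is invariant to input ordering
    return (-d.confidence, d.fold_id, d.class_label,
            d.box.x_min, d.box.y_min, d.box.width, d.box.height)


def merge_folds(
    detections: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> list[Detection]:
    """Deduplicate one image side's detections across folds by greedy NMS.

    When two candidates overlap with IoU strictly greater than
    ``iou_threshold``, only the higher-confidence one is retained.  Merging is
    class-agnostic.  Output order is by descending confidence with
    deterministic tie-breaks, so the result does not depend on input order.
    """
    if not detections:
        return []
    keys = {(d.image_id, d.side) for d in detections}
    if len(keys) > 1:
        raise ValueError(f"merge_folds expects a single image side, got {sorted(keys)}")
    ordered = sorted(detections, key=_sort_key)
    kept: list[Detection] = []
    for cand in ordered:
        if all(iou(cand.box, k.box) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def match_to_truth(
    detections: Sequence[Detection],
    truths: Sequence[GroundTruth],
    iou_match: float = 0.5,
) -> MatchResult:
    """Label detections TP/FP against class-matched ground truth.

    One-to-one greedy matching by descending confidence: a detection is a
    true positive iff it overlaps an as-yet-unmatched truth of the same class
    with IoU >= ``iou_match`` (the highest-IoU such truth is consumed).
    Unmatched truths are false negatives.
    """
    ordered = sorted(detections, key=_sort_key)
    matched_truth: set[int] = set()
    is_tp: list[bool] = []
    for det in ordered:
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if j in matched_truth or t.class_label != det.class_label:
                continue
            if t.image_id != det.image_id or t.side != det.side:
                continue
            v = iou(det.box, t.box)
            if v >= iou_match and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_truth.add(best_j)
            is_tp.append(True)
        else:
            is_tp.append(False)
    return MatchResult(ordered, is_tp, len(truths))


def sweep_thresholds(
    match: MatchResult,
    class_label: str = "",
    fold_id: int = 0,
    grid: np.ndarray | None = None,
) -> PerformanceCurve:
    """Compute precision/recall/F1 over a confidence-threshold grid.

    TP/FP status of each detection is fixed by the threshold-0 matching;
    thresholds only filter detections by confidence (kept when
    ``confidence >= t``).  Precision is NaN (undefined) at thresholds
    retaining no detections; F1 is 0 when precision and recall are both 0,
    NaN when precision is undefined.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0, 0.01), 10)  # 0 .. 0.99
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    conf = np.array([d.confidence for d in match.detections])
    tp_flag = np.array(match.is_tp, dtype=bool)
    n_truth = match.n_truth
    precision = np.full(grid.size, np.nan)
    recall = np.full(grid.size, np.nan)
    f1 = np.full(grid.size, np.nan)
    for i, t in enumerate(grid):
        keep = conf >= t
        tp = int(np.sum(tp_flag & keep))
        fp = int(np.sum(~tp_flag & keep))
        if tp + fp > 0:
            precision[i] = tp / (tp + fp)
        if n_truth > 0:
            recall[i] = tp / n_truth
        if tp + fp > 0 and n_truth > 0:
            p, r = precision[i], recall[i]
            f1[i] = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return PerformanceCurve(class_label, fold_id, grid, precision, recall, f1, n_truth)


def select_threshold(curve: PerformanceCurve) -> float:
    """Pick the optimal confidence threshold from a performance curve.

    Maximizes precision; ties are broken by higher F1, then by the lower
    threshold (earliest grid point).  Undefined (NaN) precisions are never
    eligible.  Raises if the whole curve is undefined (uncalibratable class).
    """
    defined = ~np.isnan(curve.precision)
    if not defined.any():
        raise ValueError(
            f"class {curve.class_label!r} fold {curve.fold_id}: no threshold "
            "retains any detection; class cannot be calibrated"
        )
    p = np.where(defined, curve.precision, -np.inf)
    f = np.where(np.isnan(curve.f1), -np.inf, curve.f1)
    best = max(
        range(curve.thresholds.size),
        key=lambda i: (p[i], f[i], -curve.thresholds[i]),
    )
    return float(curve.thresholds[best])


def calibrate(
    detections: Sequence[Detection],
    truths: Sequence[GroundTruth],
    classes: Sequence[str] | None = None,
    n_folds: int = 5,
    iou_match: float = 0.5,
    grid: np.ndarray | None = None,
) -> tuple[dict[str, ClassCalibration], list[PerformanceCurve]]:
    """Per-class, per-fold threshold calibration against held-out truth.

    Returns calibrations keyed by class plus the full set of performance
    curves (one per class x fold).  Classes with no detection in a fold get
    no entry for that fold; a class with no calibratable fold at all raises.
    """
    if classes is None:
        classes = sorted({t.class_label for t in truths} | {d.class_label for d in detections})
    # group per image side so matching stays linear in the dataset size
    det_by_key: dict[tuple, list[Detection]] = {}
    for d in detections:
        det_by_key.setdefault((d.class_label, d.fold_id, d.image_id, d.side), []).append(d)
    truth_by_key: dict[tuple, list[GroundTruth]] = {}
    for t in truths:
        truth_by_key.setdefault((t.class_label, t.image_id, t.side), []).append(t)
    curves: list[PerformanceCurve] = []
    calibrations: dict[str, ClassCalibration] = {}
    for cls in classes:
        n_cls_truth = sum(len(v) for k, v in truth_by_key.items() if k[0] == cls)
        images = sorted(
            {k[2:] for k in det_by_key if k[0] == cls}
            | {k[1:] for k in truth_by_key if k[0] == cls}
        )
        fold_thresholds: dict[int, float] = {}
        for fold in range(1, n_folds + 1):
            all_dets: list[Detection] = []
            all_tp: list[bool] = []
            for img, side in images:
                dets = det_by_key.get((cls, fold, img, side), [])
                if not dets:
                    continue
                m = match_to_truth(dets, truth_by_key.get((cls, img, side), []),
                                   iou_match=iou_match)
                all_dets.extend(m.detections)
                all_tp.extend(m.is_tp)
            if not all_dets and n_cls_truth == 0:
                continue
            match = MatchResult(all_dets, all_tp, n_cls_truth)
            curve = sweep_thresholds(match, cls, fold, grid=grid)
            curves.append(curve)
            try:
                fold_thresholds[fold] = select_threshold(curve)
            except ValueError:
                continue  # fold produced no detections for this class
        calibrations[cls] = ClassCalibration(cls, fold_thresholds)
    return calibrations, curves


# Lifecycle assignment: aquatic = at least one aquatic ontogenetic stage.
AQUATIC_TAXA = ("Ephemeroptera", "Nematocera", "Trichoptera")
TERRESTRIAL_TAXA = ("Brachycera", "Coleoptera", "Hemiptera", "Hymenoptera")
DEFAULT_LIFECYCLES: dict[str, str] = {
    **{t: "aquatic" for t in AQUATIC_TAXA},
    **{t: "terrestrial" for t in TERRESTRIAL_TAXA},
}


def assign_lifecycle(
    class_label: str,
    extra: Mapping[str, str] | None = None,
) -> str:
    """Map a taxon to its lifecycle group (terrestrial or aquatic).

    The built-in mapping covers the seven retained sticky-trap taxa; further
    taxa can be supplied via ``extra``.  Unknown classes raise.
    """
    table = dict(DEFAULT_LIFECYCLES)
    if extra:
        for k, v in extra.items():
            if v not in ("terrestrial", "aquatic"):
                raise ValueError(f"lifecycle for {k!r} must be terrestrial or aquatic, got {v!r}")
            table[k] = v
    try:
        return table[class_label]
    except KeyError:
        raise KeyError(
            f"no lifecycle mapping for class {class_label!r}; "
            "supply one via the extra mapping"
        ) from None


def apply_exclusions(
    calibrations: Mapping[str, ClassCalibration],
    training_counts: Mapping[str, int],
    insect_flags: Mapping[str, bool],
    min_training: int = 30,
) -> dict[str, ClassCalibration]:
    """Apply the class-exclusion rules and record the reason per class.

    A class is excluded iff it is not an insect, has fewer than
    ``min_training`` training annotations (strict), or achieved its maximal
    precision at threshold 0 in every calibrated fold.  Reason precedence:
    non_insect > under_30_training > threshold_zero.
    """
    out: dict[str, ClassCalibration] = {}
    for cls, cal in calibrations.items():
        if cls not in training_counts:
            raise KeyError(f"missing training annotation count for class {cls!r}")
        n_train = int(training_counts[cls])
        reason = "none"
        if not insect_flags.get(cls, True):
            reason = "non_insect"
        elif n_train < min_training:
            reason = "under_30_training"
        elif cal.fold_thresholds and all(t == 0.0 for t in cal.fold_thresholds.values()):
            reason = "threshold_zero"
        out[cls] = ClassCalibration(
            class_label=cls,
            fold_thresholds=dict(cal.fold_thresholds),
            n_training_annotations=n_train,
            is_insect=insect_flags.get(cls, True),
            retained=(reason == "none"),
            exclusion_reason=reason,
        )
    return out


def apply_thresholds(
    detections: Sequence[Detection],
    calibrations: Mapping[str, ClassCalibration],
) -> list[Detection]:
    """Filter detections fold-wise by each class's per-fold threshold.

    Detections of excluded classes are dropped; detections whose class has no
    threshold for their fold are dropped (uncalibrated fold).
    """
    kept = []
    for d in detections:
        cal = calibrations.get(d.class_label)
        if cal is None or not cal.retained:
            continue
        thr = cal.fold_thresholds.get(d.fold_id)
        if thr is None:
            continue
        if d.confidence >= thr:
            kept.append(d)
    return kept


def build_trait_table(
    detections: Sequence[Detection],
    image_to_trap: Mapping[str, str],
) -> pd.DataFrame:
    """Aggregate final detections into per-trap abundance and body size.

    Abundance is the count of retained detections per trap per taxon summed
    over both trap sides; body size is the maximum bounding-box area (px^2)
    among them (absent — NaN — when abundance is 0).  Every image id must map
    to a trap.
    """
    rows = []
    for d in detections:
        if d.image_id not in image_to_trap:
            raise KeyError(f"detection on unmapped image {d.image_id!r}")
        rows.append(
            {
                "trap_id": image_to_trap[d.image_id],
                "taxon": d.class_label,
                "area": d.box.area,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["trap_id", "taxon", "abundance", "max_box_area"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["trap_id", "taxon"])
        .agg(abundance=("area", "size"), max_box_area=("area", "max"))
        .reset_index()
    )
    return out


def mean_average_precision(curves: Iterable[PerformanceCurve]) -> float:
    """Informational mAP@0.5 across classes/folds (11-point interpolation).

    Reported for model-quality description only; never used in calibration.
    """
    aps = []
    for c in curves:
        ok = ~np.isnan(c.precision) & ~np.isnan(c.recall)
        if not ok.any():
            continue
        p, r = c.precision[ok], c.recall[ok]
        ap = 0.0
        for rt in np.linspace(0, 1, 11):
            mask = r >= rt
            ap += (p[mask].max() if mask.any() else 0.0) / 11
        aps.append(ap)
    if not aps:
        return math.nan
    return float(np.mean(aps))
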