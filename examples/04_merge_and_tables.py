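"""Deduplicate ensemble detections and build the trap x taxon trait table.

Five folds see (almost) the same insects; overlapping boxes with IoU > 0.5
are merged keeping the highest-confidence call, then counts and maximum
bounding-box areas are aggregated per trap over both photograph sides.
"""

from trapdiv import build_trait_table, merge_folds
from trapdiv.boxes import Box
from trapdiv.detect import Detection

detections = [
    # the same insect seen by three folds (heavily overlapping boxes)
    Detection("T1_A", "A", 1, "Nematocera", Box(100, 100, 40, 40), 0.93),
    Detection("T1_A", "A", 2, "Nematocera", Box(103, 99, 40, 40), 0.88),
    Detection("T1_A", "A", 3, "Coleoptera", Box(101, 102, 40, 40), 0.72),
    # a second insect elsewhere on the same side
    Detection("T1_A", "A", 2, "Coleoptera", Box(800, 500, 90, 60), 0.81),
]
merged = merge_folds(detections, iou_threshold=0.5)
print(f"{len(detections)} raw detections -> {len(merged)} after cross-fold merging")
for d in merged:
    print(f"  kept {d.class_label} (fold {d.fold_id}, confidence {d.confidence})")

table = build_trait_table(merged, {"T1_A": "T1"})
print(table.to_string(index=False))
# abundance counts retained detections per trap and taxon; max_box_area
# (pixels^2) is the body-size proxy: the largest individual seen at the trap.
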