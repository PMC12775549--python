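"""Calibrate per-class confidence thresholds against annotations.

Simulates a five-fold detection ensemble with separated true/false-positive
confidence distributions (Beta(8,2) vs Beta(2,8)), sweeps thresholds 0-0.99,
and picks the precision-maximizing threshold per class and fold.
"""

import numpy as np

from trapdiv import calibrate
from trapdiv.boxes import Box
from trapdiv.detect import GroundTruth
from trapdiv.synthio import DetectionErrorModel, generate_detections

truths, image_ids, tid = [], [], 0
for i in range(12):
    image_ids.append(f"T{i}_A")
    for j in range(6):
        cls = ["Nematocera", "Coleoptera", "Hemiptera"][j % 3]
        truths.append(GroundTruth(f"T{i}_A", "A", cls,
                                  Box(700.0 * (j % 6), 900.0 * (j // 3), 80, 80), tid))
        tid += 1

model = DetectionErrorModel(miss_rate=0.2, fp_rate=2.0, box_jitter=2.0)
detections, _ = generate_detections(truths, image_ids, model, seed=4)
calibrations, curves = calibrate(detections, truths)
for cls, cal in sorted(calibrations.items()):
    thr = np.array(sorted(cal.fold_thresholds.values()))
    print(f"{cls:12s} per-fold thresholds: {np.round(thr, 2)}")
# Thresholds land between the false-positive mode (0.125) and true-positive
# mode (0.875): the calibration recovers the confidence separation the
# generator planted.
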