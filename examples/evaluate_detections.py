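"""Detection-evaluation metrics on a worked micro-example.

Builds a tiny prediction set by hand and walks through IoU, the
precision-recall curve, average precision, and the mAP grids, then shows
the duration-MAE comparison of two ethogram tables.
"""

from feedtrack import (
    Behavior,
    BoxPrediction,
    BoxTruth,
    ConfusionCounts,
    DurationSummary,
    average_precision,
    duration_mae,
    iou,
    map_range,
    prf1,
)

# two ground-truth boxes; three predictions: TP, FP, TP by confidence order
gt = [BoxTruth(0, 0, (0, 0, 10, 10)), BoxTruth(1, 0, (50, 50, 10, 10))]
preds = [
    BoxPrediction(0, 0, (0, 0, 10, 10), 0.9),
    BoxPrediction(0, 0, (300, 300, 10, 10), 0.8),
    BoxPrediction(1, 0, (50, 50, 10, 10), 0.7),
]
print("IoU of the matched pair:", iou(preds[0].box, gt[0].box))
ap = average_precision(preds, gt)[0]
print(f"AP (all-point interpolation): {ap:.4f}  (= 5/6 from the PR curve)")

m50, m5095 = map_range(preds, gt)
print(f"mAP@0.5 = {m50:.4f}, mAP@0.5:0.95 = {m5095:.4f}")

r = prf1(ConfusionCounts(tp=8, tn=5, fp=2, fn=1))
print(f"accuracy={r.accuracy:.4f} precision={r.precision:.4f} "
      f"recall={r.recall:.4f} F1={r.f1:.4f}")

est = [DurationSummary(0, Behavior.FEEDING, 500, 1.0),
       DurationSummary(0, Behavior.PICKING, 1000, 2.0)]
tru = [DurationSummary(0, Behavior.FEEDING, 1000, 2.0),
       DurationSummary(0, Behavior.PICKING, 3000, 6.0)]
print(f"duration MAE: {duration_mae(est, tru):.2f} min "
      "(mean of |1-2| and |2-6|)")
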