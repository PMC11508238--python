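"""Score a detection stream against ground truth with AP / mAP.

AP is 101-point interpolated average precision; mAP averages over IoU
thresholds 0.50-0.95 and then over categories.
"""

import icucount as ic
from icucount.evaluation import mean_average_precision

gt = ic.simulate_ground_truth(ic.SimulationConfig(duration_frames=300, seed=7))
dets = ic.simulate_detections(gt, ic.NoiseConfig(), seed=8)

result = mean_average_precision(dets, gt.all_objects())
for cat, r in result["per_category"].items():
    ap50 = r["ap_by_iou"][0.5]
    print(f"{cat:9s} AP@0.50 {ap50:.3f}   AP@[0.50:0.95] {r['map']:.3f}")
print(f"mAP (all categories): {result['map']:.3f}")

# AP@0.50 reflects "did we find the person"; the stricter averaged mAP
# also punishes loose localization (the simulator's jitter), so it is
# systematically lower.
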