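# icucount

People counting for ICU room monitoring by counting-by-detection:
given a 1 frame-per-second stream of person detections (bounding boxes
with class probabilities, confidences and appearance embeddings), the
package estimates how many **patients**, **clinicians** and **visitors**
are in the room at every moment, and summarizes how long each role is
present around bedside delirium assessments (CAM-ICU / CAM-ICU-7).

It is written for researchers studying ambient monitoring in critical
care: the kind of question it answers is "does clinician or visitor
presence around an assessment differ between delirious and non-delirious
patients?" — without storing a single image pixel.

Three counting methods are implemented and compared:

1. **Single-frame** — count the admitted detections per category in each
   frame: `Out_i = Count(B_i)`, with a detection's category the argmax of
   its class probabilities and admission gated on confidence ≥ 0.3.
2. **Multi-frame** — average the single-frame counts over a window of
   F/2 frames either side of the key frame (default F = 4, a 5-frame
   window), smoothing transient misses and false alarms.
3. **Tracking-to-count** — link detections into trajectories with a
   two-stage tracker (appearance affinity via cosine similarity +
   Hungarian assignment, then IoU against Kalman-predicted boxes),
   give each trajectory one category by the argmax of the summed
   class-probability vectors over its entries, and count trajectories
   active per frame, bridging detection gaps of up to `max_age` frames.

Because ICU video cannot be shared, the package includes a seeded
**simulator** that generates ground-truth room scenes (stationary
patient, clinicians/visitors entering, wandering and leaving) and
corrupts them with realistic detector noise (misses, occlusion
surcharge, false positives, localization jitter, clinician↔visitor
confusion, noisy appearance embeddings).  An **evaluation** module
provides IoU, 101-point interpolated AP / mAP over IoU 0.50–0.95, and
counting accuracy / MAE / MRE / MSE / RMSE.  See `docs/methods.md` for
the full model description.

## Worked example

```python
import icucount as ic

# a 30-minute scene: stationary patient, 6 clinician and 4 visitor visits
sim = ic.SimulationConfig(duration_frames=1800, seed=0)
gt = ic.simulate_ground_truth(sim)
dets = ic.simulate_detections(gt, ic.NoiseConfig(), seed=1)  # pinned noise
truth = ic.ground_truth_counts(gt)

single = ic.counts_over_sequence(dets, "single")
multi = ic.counts_over_sequence(dets, "multi")
tracking, trajectories = ic.count_by_tracking(dets)

for name, pred in [("single", single), ("multi", multi), ("tracking", tracking)]:
    acc = ic.counting_accuracy(pred, truth)
    mae = ic.regression_errors(pred, truth)
    print(name, {c: (round(acc[c], 1), round(mae[c]["mae"], 3))
                 for c in ("patient", "clinician", "visitor")})
```

prints (accuracy %, MAE) per category:

```
single {'patient': (98.3, 0.017), 'clinician': (71.8, 0.295), 'visitor': (62.7, 0.414)}
multi {'patient': (99.6, 0.017), 'clinician': (87.8, 0.222), 'visitor': (72.9, 0.345)}
tracking {'patient': (98.3, 0.017), 'clinician': (97.9, 0.021), 'visitor': (98.8, 0.012)}
```

Read: the stationary patient is counted equally well by all three
methods, while for the moving categories windowed averaging reduces the
error of single-frame counting and tracking reduces it much further —
trajectory category voting fixes clinician/visitor confusion and gap
bridging rides out occlusions.

The `examples/` directory holds one short script per capability
(simulation, counting, tracking, detection evaluation, occupancy
analysis, benchmarking), each printing the numbers it computes and a
line on what they mean.

## Command line

Every stage is also a subcommand of the `icucount` console script:

```sh
icucount simulate --config sim.yaml --out-gt gt.json --out-det det.json
icucount count --detections det.json --method multi --window 4 --out counts.csv
icucount track --detections det.json --out-traj traj.txt --out-counts counts.csv
icucount evaluate --pred counts.csv --truth gt.counts.csv --out metrics.json
icucount evaluate-detection --det det.json --truth gt.json --out ap.json
icucount occupancy --counts counts.csv --assessments assessments.csv --out occ.csv
icucount benchmark compare --out report.json
icucount pipeline --config pipeline.yaml --out-dir bundle/
```

Detections and annotations travel as COCO-style JSON (boxes `[x, y, w,
h]` top-left, plus `class_probs` / `confidence` / `appearance`
extensions), trajectories as MOT-Challenge CSV, counts as plain CSV.

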