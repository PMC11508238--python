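"""Simulate an ICU room scene and corrupt it with detector noise.

Generates a 10-minute 1 fps scene (stationary patient, a few clinician
and visitor visits), then produces the noisy detection stream a trained
person detector would emit.
"""

import icucount as ic

sim = ic.SimulationConfig(duration_frames=600, n_clinician_visits=3,
                          n_visitor_visits=2, seed=42)
gt = ic.simulate_ground_truth(sim)
dets = ic.simulate_detections(gt, ic.NoiseConfig(), seed=43)

n_truth = sum(len(f) for f in gt.frames)
n_det = sum(len(f) for f in dets)
print(f"ground truth: {len(gt.identities)} identities, {n_truth} object-frames")
print(f"detections:   {n_det} boxes over {len(dets)} frames")
print(f"truth counts in frame 300: {ic.ground_truth_counts(gt).loc[300].to_dict()}")

# n_det < n_truth because ~20% of moving-person frames are missed (more
# under occlusion); a few extra boxes are false positives.
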