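"""End-to-end pipeline: simulate -> detect -> count -> track -> evaluate
(-> occupancy when assessments are supplied).

Every stage writes its output in the declared interchange format and
logs line-oriented key=value records.  The bundle is deterministic under
a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .benchmark import scene_and_noise_seeds
from .config import PipelineConfig
from .counting import counts_over_sequence
from .evaluation import counting_accuracy, regression_errors
from .io import save_counts, save_detection_sequence, save_ground_truth, save_trajectories
from .occupancy import filter_aligned, group_durations, load_assessments, segment_presence
from .simulate import ground_truth_counts, simulate_detections, simulate_ground_truth
from .tracking import count_by_tracking

logger = logging.getLogger("icucount")


def _log(stage: str, **kv) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; returns a mapping artifact name -> file path."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    scene_seed, noise_seed = scene_and_noise_seeds(config.seed)
    sim_cfg = config.simulation
    sim_cfg.seed = scene_seed
    gt = simulate_ground_truth(sim_cfg)
    _log("simulate", frames=len(gt.frames), identities=len(gt.identities), seed=scene_seed)
    gt_path = outdir / "gt.json"
    save_ground_truth(
        gt.all_objects(), gt_path, frame_indices=range(len(gt.frames)),
        frame_size=sim_cfg.frame_size, fps=sim_cfg.fps,
    )
    artifacts["ground_truth"] = str(gt_path)

    dets = simulate_detections(gt, config.noise, noise_seed)
    _log("detect", frames=len(dets), detections=sum(len(f) for f in dets), seed=noise_seed)
    det_path = outdir / "detections.json"
    save_detection_sequence(dets, det_path)
    artifacts["detections"] = str(det_path)

    truth_counts = ground_truth_counts(gt)
    save_counts(truth_counts, outdir / "counts_truth.csv")
    artifacts["counts_truth"] = str(outdir / "counts_truth.csv")

    metrics: dict = {"methods": {}}
    if len(dets) == 0:
        _log("count", frames=0)
        (outdir / "metrics.json").write_text(json.dumps(metrics, sort_keys=True, indent=2))
        artifacts["metrics"] = str(outdir / "metrics.json")
        return artifacts

    preds = {
        "single": counts_over_sequence(dets, "single", config.counting),
        "multi": counts_over_sequence(dets, "multi", config.counting),
    }
    tracking_counts, trajectories = count_by_tracking(dets, config.tracker)
    preds["tracking"] = tracking_counts
    traj_path = outdir / "trajectories.txt"
    save_trajectories(trajectories, traj_path)
    artifacts["trajectories"] = str(traj_path)
    _log("track", trajectories=len(trajectories))

    for method, pred in preds.items():
        path = outdir / f"counts_{method}.csv"
        save_counts(pred, path)
        artifacts[f"counts_{method}"] = str(path)
        acc = counting_accuracy(pred, truth_counts, config.evaluation)
        errs = regression_errors(pred, truth_counts, config.evaluation)
        metrics["methods"][method] = {
            cat: {"accuracy": acc[cat], **errs[cat]} for cat in acc
        }
        _log("evaluate", method=method,
             **{f"acc_{c}": round(acc[c], 2) for c in acc})
    cfg_dict = config.to_dict()
    cfg_dict.pop("output_dir", None)  # environment detail, not part of the science
    metrics["config"] = cfg_dict
    metrics["mre_zero_policy"] = config.evaluation.mre_zero_policy
    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, sort_keys=True, indent=2))
    artifacts["metrics"] = str(metrics_path)

    occ = config.occupancy
    if occ.assessments_path:
        assessments = load_assessments(occ.assessments_path)
        retained = filter_aligned(assessments, occ.max_offset_minutes)
        _log("occupancy", assessments=len(assessments), retained=len(retained))
        summaries = [
            segment_presence(
                tracking_counts, a, segment_seconds=occ.segment_seconds,
                fps=sim_cfg.fps, duration_mode=occ.duration_mode,
                presence_threshold=occ.presence_threshold,
            )
            for a in retained
        ]
        table = group_durations(summaries, retained, occ.grouping)
        occ_path = outdir / "occupancy.csv"
        table.to_csv(occ_path)
        artifacts["occupancy"] = str(occ_path)
    return artifacts
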