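"""Readers and writers for the interchange formats the pipeline touches.

Three dialects are supported:

* detections / ground-truth annotations: COCO-style JSON with ``images[]``,
  ``annotations[]`` and ``categories[]``.  Boxes are stored as
  ``[x, y, w, h]`` with the top-left corner per COCO convention and
  converted to center form at load time.  Detection annotations carry the
  extensions ``class_probs``, ``confidence`` and ``appearance``;
  ground-truth annotations carry ``identity``.
* detections as flat CSV (one row per detection; empty frames keep a row
  with blank detection fields so that zero-detection frames survive a
  round trip).
* trajectories as MOT-Challenge CSV:
  ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,category,-1,-1``.

Counts tables travel as CSV with columns
``frame_index,patient,clinician,visitor``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CATEGORY_NAMES,
    BoundingBox,
    Category,
    Detection,
    FrameDetections,
    GroundTruthObject,
    box_to_corners,
)

if TYPE_CHECKING:  # pragma: no cover
    from .tracking import Trajectory


class ValidationError(ValueError):
    """A record in an input file violates a domain invariant."""


def _coco_categories() -> list[dict]:
    return [{"id": int(c), "name": c.label} for c in Category]


def _box_to_coco(box: BoundingBox) -> list[float]:
    x1, y1, _, _ = box_to_corners(box)
    return [x1, y1, box.w, box.h]


def _box_from_coco(bbox: Sequence[float]) -> BoundingBox:
    x, y, w, h = (float(v) for v in bbox)
    return BoundingBox(cx=x + w / 2.0, cy=y + h / 2.0, w=w, h=h)


# ---------------------------------------------------------------------------
# Detections: COCO-style JSON
# ---------------------------------------------------------------------------

def save_detection_sequence(
    sequence: Sequence[FrameDetections], path: str | Path, format: str = "coco-json"
) -> None:
    """Write a detection sequence in the declared dialect."""
    path = Path(path)
    if format == "coco-json":
        _save_detections_coco(sequence, path)
    elif format == "csv":
        _save_detections_csv(sequence, path)
    else:
        raise ValueError(f"unknown detection format: {format!r}")


def load_detection_sequence(path: str | Path, format: str = "coco-json") -> list[FrameDetections]:
    """Load a detection sequence; frames come back sorted by frame_index,
    zero-detection frames preserved as empty entries."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "coco-json":
        return _load_detections_coco(path)
    if format == "csv":
        return _load_detections_csv(path)
    raise ValueError(f"unknown detection format: {format!r}")


def _save_detections_coco(sequence: Sequence[FrameDetections], path: Path) -> None:
    images = []
    annotations = []
    ann_id = 1
    for frame in sequence:
        h, w = frame.frame_size
        images.append(
            {
                "id": int(frame.frame_index),
                "frame_index": int(frame.frame_index),
                "timestamp": float(frame.timestamp),
                "height": int(h),
                "width": int(w),
            }
        )
        for det in frame.detections:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": int(frame.frame_index),
                    "bbox": _box_to_coco(det.box),
                    "category_id": int(det.category),
                    "class_probs": [float(p) for p in det.class_probs],
                    "confidence": float(det.confidence),
                    "appearance": [float(v) for v in det.appearance],
                }
            )
            ann_id += 1
    payload = {"images": images, "annotations": annotations, "categories": _coco_categories()}
    path.write_text(json.dumps(payload))


def _load_detections_coco(path: Path) -> list[FrameDetections]:
    payload = json.loads(path.read_text())
    frames: dict[int, FrameDetections] = {}
    for img in payload.get("images", []):
        idx = int(img["frame_index"] if "frame_index" in img else img["id"])
        frames[int(img["id"])] = FrameDetections(
            frame_index=idx,
            timestamp=float(img.get("timestamp", idx)),
            detections=[],
            frame_size=(int(img["height"]), int(img["width"])),
        )
    for rec_no, ann in enumerate(payload.get("annotations", [])):
        image_id = int(ann["image_id"])
        if image_id not in frames:
            raise ValidationError(f"annotation {rec_no} references unknown image_id {image_id}")
        frame = frames[image_id]
        try:
            det = Detection(
                box=_box_from_coco(ann["bbox"]),
                class_probs=np.asarray(ann["class_probs"], dtype=float),
                confidence=float(ann["confidence"]),
                appearance=np.asarray(ann["appearance"], dtype=float),
            )
        except (ValueError, KeyError) as exc:
            raise ValidationError(
                f"invalid detection record {rec_no} in frame {frame.frame_index}: {exc}"
            ) from exc
        frame.detections.append(det)
    return [frames[k] for k in sorted(frames, key=lambda k: frames[k].frame_index)]


# ---------------------------------------------------------------------------
# Detections: CSV
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "frame_index",
    "timestamp",
    "height",
    "width",
    "cx",
    "cy",
    "w",
    "h",
    "p_patient",
    "p_clinician",
    "p_visitor",
    "confidence",
    "appearance",
]


def _save_detections_csv(sequence: Sequence[FrameDetections], path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for frame in sequence:
            h, w = frame.frame_size
            base = [frame.frame_index, repr(frame.timestamp), h, w]
            if not frame.detections:
                writer.writerow(base + [""] * 9)
                continue
            for det in frame.detections:
                writer.writerow(
                    base
                    + [repr(float(v)) for v in (det.box.cx, det.box.cy, det.box.w, det.box.h)]
                    + [repr(float(p)) for p in det.class_probs]
                    + [repr(float(det.confidence))]
                    + [" ".join(repr(float(v)) for v in det.appearance)]
                )


def _load_detections_csv(path: Path) -> list[FrameDetections]:
    frames: dict[int, FrameDetections] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for rec_no, row in enumerate(reader):
            idx = int(row["frame_index"])
            if idx not in frames:
                frames[idx] = FrameDetections(
                    frame_index=idx,
                    timestamp=float(row["timestamp"]),
                    detections=[],
                    frame_size=(int(row["height"]), int(row["width"])),
                )
            if row["cx"] == "":  # placeholder row for an empty frame
                continue
            try:
                det = Detection(
                    box=BoundingBox(
                        cx=float(row["cx"]), cy=float(row["cy"]),
                        w=float(row["w"]), h=float(row["h"]),
                    ),
                    class_probs=np.array(
                        [float(row["p_patient"]), float(row["p_clinician"]), float(row["p_visitor"])]
                    ),
                    confidence=float(row["confidence"]),
                    appearance=np.array([float(v) for v in row["appearance"].split()]),
                )
            except ValueError as exc:
                raise ValidationError(
                    f"invalid detection record {rec_no} in frame {idx}: {exc}"
                ) from exc
            frames[idx].detections.append(det)
    return [frames[k] for k in sorted(frames)]


# ---------------------------------------------------------------------------
# Ground truth annotations (COCO-style JSON with identities)
# ---------------------------------------------------------------------------

def save_ground_truth(
    objects: Iterable[GroundTruthObject],
    path: str | Path,
    frame_indices: Iterable[int] | None = None,
    frame_size: tuple[int, int] = (1044, 1392),
    fps: float = 1.0,
) -> None:
    """Write ground-truth annotations.  ``frame_indices`` lists every frame
    of the stream (so frames without people are preserved); when omitted it
    is inferred from the annotated frames."""
    objects = list(objects)
    if frame_indices is None:
        frame_indices = sorted({o.frame_index for o in objects})
    h, w = frame_size
    images = [
        {"id": int(i), "frame_index": int(i), "timestamp": float(i) / fps,
         "height": int(h), "width": int(w)}
        for i in frame_indices
    ]
    annotations = [
        {
            "id": n + 1,
            "image_id": int(o.frame_index),
            "bbox": _box_to_coco(o.box),
            "category_id": int(o.category),
            "identity": int(o.identity),
        }
        for n, o in enumerate(objects)
    ]
    payload = {"images": images, "annotations": annotations, "categories": _coco_categories()}
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> tuple[list[GroundTruthObject], list[int]]:
    """Load ground-truth annotations.  Returns (objects, frame_indices)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = json.loads(path.read_text())
    frame_indices = sorted(int(img.get("frame_index", img["id"])) for img in payload["images"])
    objects = []
    for rec_no, ann in enumerate(payload.get("annotations", [])):
        try:
            objects.append(
                GroundTruthObject(
                    identity=int(ann["identity"]),
                    category=Category(int(ann["category_id"])),
                    box=_box_from_coco(ann["bbox"]),
                    frame_index=int(ann["image_id"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"invalid ground-truth record {rec_no}: {exc}") from exc
    objects.sort(key=lambda o: (o.frame_index, o.identity))
    return objects, frame_indices


# ---------------------------------------------------------------------------
# Trajectories: MOT-Challenge CSV
# ---------------------------------------------------------------------------

MOT_HEADER = "frame,id,bb_left,bb_top,bb_width,bb_height,conf,category,x,y"


def save_trajectories(trajectories: Iterable["Trajectory"], path: str | Path) -> None:
    """Write finalized trajectories in the MOT-Challenge dialect, one line
    per (trajectory, frame), sorted by frame then trajectory id."""
    rows = []
    for traj in trajectories:
        cat = int(traj.category())
        for entry in traj.entries:
            x1, y1, _, _ = box_to_corners(entry.box)
            rows.append(
                (entry.frame_index, traj.id, x1, y1, entry.box.w, entry.box.h, 1.0, cat)
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    with Path(path).open("w", newline="") as fh:
        fh.write(MOT_HEADER + "\n")
        for frame, tid, left, top, w, h, conf, cat in rows:
            fh.write(f"{frame},{tid},{left:.2f},{top:.2f},{w:.2f},{h:.2f},{conf:.2f},{cat},-1,-1\n")


# ---------------------------------------------------------------------------
# Counts tables
# ---------------------------------------------------------------------------

def counts_to_frame(counts: dict[int, "np.ndarray"] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a per-frame counts mapping into the canonical DataFrame
    (index frame_index, columns patient/clinician/visitor)."""
    if isinstance(counts, pd.DataFrame):
        df = counts.copy()
    else:
        df = pd.DataFrame.from_dict(
            {k: np.asarray(v, dtype=float) for k, v in counts.items()},
            orient="index",
            columns=list(CATEGORY_NAMES),
        )
    df.index.name = "frame_index"
    return df.sort_index()


def save_counts(counts: pd.DataFrame, path: str | Path) -> None:
    df = counts_to_frame(counts)
    df.to_csv(path, index=True)


def load_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col="frame_index")
    missing = [c for c in CATEGORY_NAMES if c not in df.columns]
    if missing:
        raise ValidationError(f"counts file lacks columns: {missing}")
    return df[list(CATEGORY_NAMES)].sort_index()
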