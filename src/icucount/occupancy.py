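"""Segment-based occupancy-duration analysis around delirium assessments.

Each CAM-ICU / CAM-ICU-7 assessment anchors a 30-minute window (15
minutes either side).  The window is divided into consecutive 5-second
segments — 360 of them at 1 fps — and the mean per-category count over
each segment's frames is recorded.  A category's length of stay is then,
under the default ``indicator`` definition, 5 seconds for every segment
whose mean count reaches the presence threshold (0.5: present in at
least half the segment); under the alternative ``person-time``
definition it is the integral of the mean counts, which can exceed the
window length when several people of one category overlap.

Assessments whose recording clock disagrees with the assessment clock by
more than 30 minutes are excluded before any aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError
from .types import CATEGORY_NAMES


@dataclass(frozen=True)
class AssessmentWindow:
    """A delirium assessment and its monitoring window."""

    assessment_id: str
    assessment_time: float  # seconds since stream start
    recording_offset_min: float  # |assessment clock - camera clock|
    cam_icu_positive: bool
    cam_icu7: int
    window_half_width_min: float = 15.0

    def __post_init__(self) -> None:
        if not 0 <= self.cam_icu7 <= 7:
            raise ValueError("cam_icu7 must lie in [0, 7]")
        if self.recording_offset_min < 0:
            raise ValueError("recording_offset_min must be >= 0")


@dataclass
class OccupancySummary:
    """Per-window occupancy: segment mean counts and derived durations."""

    assessment_id: str
    segment_means: pd.DataFrame  # n_segments x 3, columns patient/clinician/visitor
    duration_minutes: dict[str, float]
    n_segments: int
    n_segments_covered: int
    partial: bool
    duration_mode: str


def filter_aligned(
    assessments: Iterable[AssessmentWindow], max_offset_minutes: float = 30.0
) -> list[AssessmentWindow]:
    """Keep assessments whose clock offset does not exceed the cap
    (boundary inclusive: exactly 30 minutes is retained)."""
    return [a for a in assessments if a.recording_offset_min <= max_offset_minutes]


def n_segments_per_window(
    window_minutes: float = 30.0, segment_seconds: float = 5.0
) -> int:
    """Number of segments a window divides into (360 for 30 min at 5 s)."""
    n = window_minutes * 60.0 / segment_seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError("window must divide evenly into segments")
    return int(round(n))


def segment_presence(
    counts: pd.DataFrame,
    window: AssessmentWindow,
    segment_seconds: float = 5.0,
    fps: float = 1.0,
    duration_mode: Literal["indicator", "person-time"] = "indicator",
    presence_threshold: float = 0.5,
) -> OccupancySummary:
    """Summarize per-frame counts over one assessment window.

    Frames missing from ``counts`` are treated as absent; a window whose
    frames are entirely outside the table raises a coverage error.
    Partial windows are flagged and their indicator durations scaled up
    by total/covered segments.
    """
    frames_per_segment = segment_seconds * fps
    if abs(frames_per_segment - round(frames_per_segment)) > 1e-9 or frames_per_segment < 1:
        raise ValueError("segment_seconds * fps must be a positive integer")
    frames_per_segment = int(round(frames_per_segment))
    window_seconds = 2.0 * window.window_half_width_min * 60.0
    n_segments = n_segments_per_window(window_seconds / 60.0, segment_seconds)

    start_frame = int(round((window.assessment_time - window.window_half_width_min * 60.0) * fps))
    n_frames = n_segments * frames_per_segment
    wanted = np.arange(start_frame, start_frame + n_frames)
    available = counts.index
    covered_mask = np.isin(wanted, available)
    if not covered_mask.any():
        raise ValidationError(
            f"assessment {window.assessment_id}: window [{wanted[0]}, {wanted[-1]}] "
            "entirely outside the counts table"
        )
    table = np.zeros((n_frames, len(CATEGORY_NAMES)))
    present = counts.reindex(wanted).to_numpy(float)
    table[covered_mask] = present[covered_mask]

    seg = table.reshape(n_segments, frames_per_segment, len(CATEGORY_NAMES)).mean(axis=1)
    seg_df = pd.DataFrame(seg, columns=list(CATEGORY_NAMES))
    seg_covered = covered_mask.reshape(n_segments, frames_per_segment).any(axis=1)
    n_covered = int(seg_covered.sum())
    partial = n_covered < n_segments
    scale = n_segments / n_covered

    durations: dict[str, float] = {}
    for k, name in enumerate(CATEGORY_NAMES):
        if duration_mode == "indicator":
            minutes = (seg[seg_covered, k] >= presence_threshold).sum() * segment_seconds / 60.0
        elif duration_mode == "person-time":
            minutes = seg[seg_covered, k].sum() * segment_seconds / 60.0
        else:
            raise ValueError(f"unknown duration_mode: {duration_mode!r}")
        durations[name] = float(minutes * scale) if partial else float(minutes)
    return OccupancySummary(
        assessment_id=window.assessment_id,
        segment_means=seg_df,
        duration_minutes=durations,
        n_segments=n_segments,
        n_segments_covered=n_covered,
        partial=partial,
        duration_mode=duration_mode,
    )


def _bucket(a: AssessmentWindow, grouping: str) -> str:
    if grouping == "cam_icu_binary":
        return "positive" if a.cam_icu_positive else "negative"
    if grouping == "cam_icu7_buckets":
        if a.cam_icu7 == 0:
            return "0"
        if a.cam_icu7 <= 2:
            return "1-2"
        return "3-7"
    raise ValueError(f"unknown grouping: {grouping!r}")


def group_durations(
    summaries: Sequence[OccupancySummary],
    assessments: Sequence[AssessmentWindow],
    grouping: Literal["cam_icu_binary", "cam_icu7_buckets"] = "cam_icu_binary",
) -> pd.DataFrame:
    """Mean per-category duration per label group.

    Returns a DataFrame indexed by group with per-category mean duration
    columns and an ``n`` column; empty groups appear with n = 0 and NaN
    means.
    """
    by_id = {a.assessment_id: a for a in assessments}
    rows = []
    for s in summaries:
        if s.assessment_id not in by_id:
            raise ValidationError(f"summary {s.assessment_id} has no retained assessment")
        rows.append({"group": _bucket(by_id[s.assessment_id], grouping), **s.duration_minutes})
    groups = (
        ["negative", "positive"] if grouping == "cam_icu_binary" else ["0", "1-2", "3-7"]
    )
    df = pd.DataFrame(rows, columns=["group", *CATEGORY_NAMES])
    out = []
    for g in groups:
        sub = df[df["group"] == g]
        rec = {"group": g, "n": len(sub)}
        for name in CATEGORY_NAMES:
            rec[name] = float(sub[name].mean()) if len(sub) else float("nan")
        out.append(rec)
    return pd.DataFrame(out).set_index("group")


# ---------------------------------------------------------------------------
# Assessment CSV I/O (columns: assessment_id, time, offset_min, cam_icu, cam_icu7)
# ---------------------------------------------------------------------------

def load_assessments(path: str | Path) -> list[AssessmentWindow]:
    df = pd.read_csv(path)
    required = {"assessment_id", "time", "offset_min", "cam_icu", "cam_icu7"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"assessments file lacks columns: {sorted(missing)}")
    return [
        AssessmentWindow(
            assessment_id=str(r.assessment_id),
            assessment_time=float(r.time),
            recording_offset_min=float(r.offset_min),
            cam_icu_positive=bool(int(r.cam_icu)),
            cam_icu7=int(r.cam_icu7),
        )
        for r in df.itertuples()
    ]


def save_assessments(assessments: Iterable[AssessmentWindow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "assessment_id": a.assessment_id,
                "time": a.assessment_time,
                "offset_min": a.recording_offset_min,
                "cam_icu": int(a.cam_icu_positive),
                "cam_icu7": a.cam_icu7,
            }
            for a in assessments
        ]
    ).to_csv(path, index=False)
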