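"""Multi-object tracker and tracking-to-count.

Association is two-stage, run once per frame:

1. appearance stage — cosine similarities between each active
   trajectory's appearance summary (an exponential moving average of its
   members' re-ID embeddings) and each admitted detection form an
   affinity matrix; a maximum-total-similarity one-to-one assignment
   (Hungarian algorithm) is computed and pairs below the similarity floor
   are dropped;
2. spatial stage — leftover trajectories and detections are matched on
   the IoU between the Kalman-predicted box and the detection box.

Matched trajectories are extended and Kalman-updated; unmatched
detections start new trajectories (confirmed immediately — at 1 fps a
person can legitimately appear in very few frames); trajectories
unmatched for more than ``max_age`` consecutive frames are terminated.

Each finalized trajectory votes for a single category: the argmax over
the entry-wise sum of its class-probability vectors, so frames where the
detector leaned the wrong way are outvoted by the rest of the track.
Tracking-based counting then counts, per frame and category, the
trajectories active at that frame, where activity bridges detection gaps
of up to ``max_age`` frames — brief occlusions do not drop the count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import counts_to_frame
from .kalman import KalmanState, kalman_init, kalman_predict, kalman_update
from .simulate import _box_iou_corners
from .types import NUM_CATEGORIES, BoundingBox, Category, Detection, FrameDetections


@dataclass
class TrackerConfig:
    appearance_min_similarity: float = 0.4
    iou_min_overlap: float = 0.3
    max_age: int = 5
    ema_momentum: float = 0.9
    confidence_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not -1.0 <= self.appearance_min_similarity <= 1.0:
            raise ValueError("appearance_min_similarity must lie in [-1, 1]")
        if not 0.0 <= self.iou_min_overlap <= 1.0:
            raise ValueError("iou_min_overlap must lie in [0, 1]")
        if not 0.0 <= self.ema_momentum <= 1.0:
            raise ValueError("ema_momentum must lie in [0, 1]")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.max_age < 0:
            raise ValueError("max_age must be >= 0")


@dataclass(frozen=True)
class TrajectoryEntry:
    frame_index: int
    box: BoundingBox
    class_probs: np.ndarray
    appearance: np.ndarray


@dataclass
class Trajectory:
    """One tracked identity: linked boxes, filter state and accumulated
    category evidence."""

    id: int
    entries: list[TrajectoryEntry]
    kalman: KalmanState
    appearance_summary: np.ndarray
    misses_since_update: int = 0
    status: str = "active"
    _prob_sum: np.ndarray = field(default_factory=lambda: np.zeros(NUM_CATEGORIES))

    @property
    def length(self) -> int:
        return len(self.entries)

    def category(self) -> Category:
        return trajectory_category(self)

    def active_frames(self) -> list[int]:
        """Frames at which the identity is considered present: entry
        frames plus every frame inside a bridged detection gap."""
        if not self.entries:
            return []
        first = self.entries[0].frame_index
        last = self.entries[-1].frame_index
        return list(range(first, last + 1))


def trajectory_category(traj: Trajectory) -> Category:
    """Category vote: argmax of the entry-wise sum of class probabilities,
    ties toward the lower index."""
    if not traj.entries:
        raise ValueError("trajectory has no entries")
    total = np.sum([e.class_probs for e in traj.entries], axis=0)
    return Category(int(np.argmax(total)))


def appearance_affinity(
    trajectories: Sequence[Trajectory], detections: Sequence[Detection]
) -> np.ndarray:
    """Cosine-similarity affinity matrix, trajectories x detections."""
    if not trajectories or not detections:
        return np.zeros((len(trajectories), len(detections)))
    T = np.stack([t.appearance_summary for t in trajectories])
    D = np.stack([d.appearance for d in detections])
    for name, M in (("trajectory", T), ("detection", D)):
        norms = np.linalg.norm(M, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError(f"zero-norm {name} appearance vector")
    return T @ D.T


def match_bipartite(
    similarity: np.ndarray, min_similarity: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Maximum-total-similarity one-to-one assignment.

    Returns (pairs, unmatched_rows, unmatched_cols); assigned pairs whose
    similarity falls below ``min_similarity`` are removed after the
    assignment and their members reported unmatched.
    """
    similarity = np.asarray(similarity, dtype=float)
    if similarity.size == 0:
        return [], list(range(similarity.shape[0])), list(range(similarity.shape[1]))
    if not np.all(np.isfinite(similarity)):
        raise ValueError("similarity matrix must be finite")
    rows, cols = linear_sum_assignment(similarity, maximize=True)
    pairs = []
    matched_rows: set[int] = set()
    matched_cols: set[int] = set()
    for r, c in zip(rows, cols):
        if similarity[r, c] >= min_similarity:
            pairs.append((int(r), int(c)))
            matched_rows.add(int(r))
            matched_cols.add(int(c))
    unmatched_rows = [r for r in range(similarity.shape[0]) if r not in matched_rows]
    unmatched_cols = [c for c in range(similarity.shape[1]) if c not in matched_cols]
    return pairs, unmatched_rows, unmatched_cols


class Tracker:
    """Online tracker state: active and finished trajectories."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.active: list[Trajectory] = []
        self.finished: list[Trajectory] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def step(self, frame: FrameDetections) -> None:
        """Process one frame; frames must arrive in increasing order."""
        cfg = self.config
        if self._last_frame is not None and frame.frame_index <= self._last_frame:
            raise ValueError(
                f"frame {frame.frame_index} out of order (last was {self._last_frame})"
            )
        self._last_frame = frame.frame_index

        admitted = [d for d in frame.detections if d.confidence >= cfg.confidence_threshold]
        for traj in self.active:
            traj.kalman = kalman_predict(traj.kalman)

        # stage 1: appearance
        sim = appearance_affinity(self.active, admitted)
        pairs, un_traj, un_det = match_bipartite(sim, cfg.appearance_min_similarity)

        # stage 2: IoU between predicted boxes and leftover detections
        if un_traj and un_det:
            iou_mat = np.zeros((len(un_traj), len(un_det)))
            for a, ti in enumerate(un_traj):
                pbox = self.active[ti].kalman.box
                for b, di in enumerate(un_det):
                    iou_mat[a, b] = _box_iou_corners(pbox, admitted[di].box)
            pairs2, un_a, un_b = match_bipartite(iou_mat, cfg.iou_min_overlap)
            pairs += [(un_traj[a], un_det[b]) for a, b in pairs2]
            un_traj = [un_traj[a] for a in un_a]
            un_det = [un_det[b] for b in un_b]

        for ti, di in pairs:
            traj, det = self.active[ti], admitted[di]
            traj.kalman = kalman_update(traj.kalman, det.box)
            traj.entries.append(
                TrajectoryEntry(
                    frame_index=frame.frame_index,
                    box=det.box,
                    class_probs=det.class_probs,
                    appearance=det.appearance,
                )
            )
            traj._prob_sum = traj._prob_sum + det.class_probs
            m = cfg.ema_momentum
            summary = m * traj.appearance_summary + (1.0 - m) * det.appearance
            traj.appearance_summary = summary / np.linalg.norm(summary)
            traj.misses_since_update = 0

        still_active: list[Trajectory] = []
        for ti, traj in enumerate(self.active):
            if ti in {p[0] for p in pairs}:
                still_active.append(traj)
                continue
            traj.misses_since_update += 1
            if traj.misses_since_update > cfg.max_age:
                traj.status = "terminated"
                self.finished.append(traj)
            else:
                still_active.append(traj)
        self.active = still_active

        for di in un_det:
            det = admitted[di]
            self.active.append(
                Trajectory(
                    id=self._next_id,
                    entries=[
                        TrajectoryEntry(
                            frame_index=frame.frame_index,
                            box=det.box,
                            class_probs=det.class_probs,
                            appearance=det.appearance,
                        )
                    ],
                    kalman=kalman_init(det.box),
                    appearance_summary=det.appearance.copy(),
                    _prob_sum=det.class_probs.copy(),
                )
            )
            self._next_id += 1

    def finalize(self) -> list[Trajectory]:
        """Terminate everything and return all trajectories sorted by id."""
        for traj in self.active:
            traj.status = "terminated"
            self.finished.append(traj)
        self.active = []
        return sorted(self.finished, key=lambda t: t.id)


def tracker_step(
    tracker: Tracker, frame: FrameDetections, config: TrackerConfig | None = None
) -> Tracker:
    """Functional wrapper: advance the tracker by one frame."""
    if config is not None:
        tracker.config = config
    tracker.step(frame)
    return tracker


def count_by_tracking(
    sequence: Sequence[FrameDetections], config: TrackerConfig | None = None
) -> tuple[pd.DataFrame, list[Trajectory]]:
    """Run the tracker over a sequence and count trajectory activity.

    Frame i's count for category c is the number of trajectories whose
    voted category is c and which are active at i (an entry at i, or i
    inside a bridged gap between entries).
    """
    config = config or TrackerConfig()
    tracker = Tracker(config)
    for frame in sequence:
        tracker.step(frame)
    trajectories = tracker.finalize()

    frame_indices = [f.frame_index for f in sequence]
    index_pos = {fi: p for p, fi in enumerate(frame_indices)}
    table = np.zeros((len(sequence), NUM_CATEGORIES))
    for traj in trajectories:
        cat = int(traj.category())
        for fi in traj.active_frames():
            if fi in index_pos:
                table[index_pos[fi], cat] += 1
    df = counts_to_frame(
        pd.DataFrame(table, index=frame_indices, columns=["patient", "clinician", "visitor"])
    )
    return df, trajectories
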