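"""Single-frame and multi-frame people counting.

Single-frame counting tallies, per category, the detections whose
confidence clears the admission threshold; a detection's category is the
argmax of its class-probability vector (ties toward the lower index).
Multi-frame counting averages the single-frame counts over a window of
F/2 frames on either side of the key frame (F even, so F+1 frames for an
interior frame), which smooths occlusion-induced misses and spurious
detections at the cost of fractional counts.  At the sequence boundaries
the window is clipped and the mean taken over the frames actually present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import counts_to_frame
from .types import NUM_CATEGORIES, CountVector, FrameDetections


@dataclass
class CountingConfig:
    """Knobs for counting-by-detection.

    ``window_size`` is F, the number of neighbouring frames pooled around
    the key frame (F/2 before, F/2 after); F = 4 gives the default
    5-frame window.  ``confidence_threshold`` admits a detection into the
    count.
    """

    confidence_threshold: float = 0.3
    window_size: int = 4
    boundary_mode: Literal["clip"] = "clip"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.window_size < 0 or self.window_size % 2 != 0:
            raise ValueError("window_size F must be an even nonnegative integer")


def count_single_frame(frame: FrameDetections, config: CountingConfig | None = None) -> CountVector:
    """Count admitted detections per category in one frame."""
    config = config or CountingConfig()
    counts = np.zeros(NUM_CATEGORIES)
    for det in frame.detections:
        if det.confidence >= config.confidence_threshold:
            counts[int(det.category)] += 1
    return CountVector.from_array(counts)


def count_multi_frame(
    sequence: Sequence[FrameDetections], i: int, config: CountingConfig | None = None
) -> CountVector:
    """Average the single-frame counts over the window centered at frame i."""
    config = config or CountingConfig()
    if not 0 <= i < len(sequence):
        raise IndexError(f"frame index {i} outside sequence of length {len(sequence)}")
    half = config.window_size // 2
    lo = max(0, i - half)
    hi = min(len(sequence) - 1, i + half)
    window = [count_single_frame(sequence[j], config).as_array() for j in range(lo, hi + 1)]
    return CountVector.from_array(np.mean(window, axis=0))


def counts_over_sequence(
    sequence: Sequence[FrameDetections],
    method: Literal["single", "multi"] = "single",
    config: CountingConfig | None = None,
) -> pd.DataFrame:
    """Per-frame counts table for a whole sequence.

    ``multi`` is computed from the single-frame table with a clipped
    moving average, which is exactly equivalent to calling
    :func:`count_multi_frame` at every index.
    """
    config = config or CountingConfig()
    single = np.array(
        [count_single_frame(f, config).as_array() for f in sequence], dtype=float
    ).reshape(len(sequence), NUM_CATEGORIES)
    if method == "single" or config.window_size == 0:
        table = single
    elif method == "multi":
        n = len(sequence)
        half = config.window_size // 2
        csum = np.vstack([np.zeros((1, NUM_CATEGORIES)), np.cumsum(single, axis=0)])
        idx = np.arange(n)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n - 1, idx + half)
        table = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    else:
        raise ValueError(f"unknown counting method: {method!r}")
    frame_idx = [f.frame_index for f in sequence]
    return counts_to_frame(pd.DataFrame(table, index=frame_idx, columns=["patient", "clinician", "visitor"]))
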