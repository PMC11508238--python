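"""Deterministic miniature detection sequences for tests and docs.

Each fixture is a short (10-100 frame) sequence constructed to exhibit
one tracking-relevant phenomenon: frames with no detections, a one-frame
occlusion gap inside an otherwise continuous track, a trajectory whose
per-frame labels sometimes disagree with its identity, and two visitors
whose boxes overlap.
"""

from __future__ import annotations

import numpy as np

from .types import BoundingBox, Category, Detection, FrameDetections

FRAME_SIZE = (1044, 1392)


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(128)
    return v / np.linalg.norm(v)


def _one_hot(category: Category) -> np.ndarray:
    p = np.zeros(3)
    p[int(category)] = 1.0
    return p


def _det(cx, cy, category, appearance, w=120.0, h=260.0, conf=0.9, probs=None) -> Detection:
    return Detection(
        box=BoundingBox(cx=cx, cy=cy, w=w, h=h),
        class_probs=_one_hot(category) if probs is None else np.asarray(probs, float),
        confidence=conf,
        appearance=appearance,
    )


def _frames(dets_by_frame: dict[int, list[Detection]], n_frames: int) -> list[FrameDetections]:
    return [
        FrameDetections(
            frame_index=i,
            timestamp=float(i),
            detections=dets_by_frame.get(i, []),
            frame_size=FRAME_SIZE,
        )
        for i in range(n_frames)
    ]


def make_fixtures(seed: int = 0) -> dict[str, list[FrameDetections]]:
    """Build the pinned fixture set; identical output for a given seed."""
    rng = np.random.default_rng(seed)
    app_clin = _unit(rng)
    app_vis1 = _unit(rng)
    app_vis2 = _unit(rng)

    # 1. empty frames: a clinician detection in most frames, none in 3 and 7
    empty_frames = _frames(
        {
            i: [_det(400 + 10 * i, 500, Category.CLINICIAN, app_clin)]
            for i in range(10)
            if i not in (3, 7)
        },
        10,
    )

    # 2. occlusion gap: one clinician walking, missing at frame 5 only
    occlusion_gap = _frames(
        {
            i: [_det(300 + 20 * i, 520, Category.CLINICIAN, app_clin)]
            for i in range(12)
            if i != 5
        },
        12,
    )

    # 3. class confusion: a clinician labelled visitor in frames 2 and 6
    confusion = {}
    for i in range(10):
        cat = Category.VISITOR if i in (2, 6) else Category.CLINICIAN
        confusion[i] = [_det(600, 400 + 5 * i, cat, app_clin)]
    class_confusion = _frames(confusion, 10)

    # 4. overlapping visitors: two visitors whose boxes overlap heavily
    overlapping = {}
    for i in range(10):
        overlapping[i] = [
            _det(700 + 6 * i, 500, Category.VISITOR, app_vis1),
            _det(760 + 6 * i, 510, Category.VISITOR, app_vis2),
        ]
    overlapping_visitors = _frames(overlapping, 10)

    return {
        "empty_frames": empty_frames,
        "occlusion_gap": occlusion_gap,
        "class_confusion": class_confusion,
        "overlapping_visitors": overlapping_visitors,
    }
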