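"""Core domain types for the ICU people-counting pipeline.

Everything downstream (simulation, counting, tracking, evaluation) works on
these containers.  Boxes are stored center-based in pixel units with the
origin at the top-left corner and y increasing downward; conversion to
corner form happens only inside geometry operations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Number of object categories (patient, clinician, visitor).
NUM_CATEGORIES = 3

#: Dimensionality of appearance (re-ID) embeddings.  The embeddings only
#: need to support cosine similarity, so the dimension is a package
#: constant rather than tied to any particular feature-extraction network.
APPEARANCE_DIM = 128

_PROB_ATOL = 1e-9


class Category(enum.IntEnum):
    """The three person categories seen in an ICU room.

    The ordering is fixed: patient(0), clinician(1), visitor(2).  Ties in
    argmax-style decisions break toward the lower index.
    """

    PATIENT = 0
    CLINICIAN = 1
    VISITOR = 2

    @property
    def label(self) -> str:
        return self.name.lower()


CATEGORY_NAMES = tuple(c.label for c in Category)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in center/width/height form (pixels)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")
        if not (np.isfinite(self.cx) and np.isfinite(self.cy)):
            raise ValueError("box center must be finite")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def aspect(self) -> float:
        """Width over height, the shape variable tracked by the Kalman filter."""
        return self.w / self.h


def box_to_corners(box: BoundingBox) -> tuple[float, float, float, float]:
    """Convert a center-form box to corner form (x1, y1, x2, y2)."""
    return (
        box.cx - box.w / 2.0,
        box.cy - box.h / 2.0,
        box.cx + box.w / 2.0,
        box.cy + box.h / 2.0,
    )


def corners_to_box(x1: float, y1: float, x2: float, y2: float) -> BoundingBox:
    """Inverse of :func:`box_to_corners`."""
    return BoundingBox(cx=(x1 + x2) / 2.0, cy=(y1 + y2) / 2.0, w=x2 - x1, h=y2 - y1)


@dataclass(frozen=True)
class Detection:
    """One detected box: geometry, per-category probabilities, confidence
    and a unit-norm appearance embedding."""

    box: BoundingBox
    class_probs: np.ndarray
    confidence: float
    appearance: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (NUM_CATEGORIES,):
            raise ValueError(f"class_probs must have length {NUM_CATEGORIES}, got {probs.shape}")
        if np.any(probs < -_PROB_ATOL):
            raise ValueError("class_probs entries must be nonnegative")
        if abs(float(probs.sum()) - 1.0) > 1e-6:
            raise ValueError(f"class_probs must sum to 1, got {probs.sum()!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        app = np.asarray(self.appearance, dtype=float)
        norm = float(np.linalg.norm(app))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"appearance must be unit norm, got |phi| = {norm}")
        object.__setattr__(self, "class_probs", probs)
        object.__setattr__(self, "appearance", app)

    @property
    def category(self) -> Category:
        """Hard label: argmax of class_probs, ties toward the lower index."""
        return Category(int(np.argmax(self.class_probs)))


@dataclass
class FrameDetections:
    """All detections for one frame of a regular (default 1 fps) stream."""

    frame_index: int
    timestamp: float
    detections: list[Detection] = field(default_factory=list)
    frame_size: tuple[int, int] = (1044, 1392)  # (H, W)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class GroundTruthObject:
    """One annotated person in one frame, with a persistent identity."""

    identity: int
    category: Category
    box: BoundingBox
    frame_index: int


@dataclass(frozen=True)
class CountVector:
    """Per-category occupancy for one frame.

    Integer-valued when produced by single-frame counting; real-valued for
    multi-frame averages and tracking-derived means.
    """

    patient: float
    clinician: float
    visitor: float

    def __post_init__(self) -> None:
        for name in ("patient", "clinician", "visitor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} count must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.patient, self.clinician, self.visitor], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CountVector":
        a = np.asarray(arr, dtype=float)
        return cls(patient=float(a[0]), clinician=float(a[1]), visitor=float(a[2]))

    def __getitem__(self, category: Category | int) -> float:
        return float(self.as_array()[int(category)])
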