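import numpy as np
import pytest

from icucount.types import BoundingBox, Category, Detection, FrameDetections


def unit_vector(rng: np.random.Generator, dim: int = 128) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def one_hot(category: Category) -> np.ndarray:
    p = np.zeros(3)
    p[int(category)] = 1.0
    return p


def make_detection(
    cx=500.0,
    cy=500.0,
    w=120.0,
    h=260.0,
    category=Category.CLINICIAN,
    confidence=0.9,
    appearance=None,
    class_probs=None,
    rng=None,
) -> Detection:
    if appearance is None:
        appearance = unit_vector(rng or np.random.default_rng(0))
    return Detection(
        box=BoundingBox(cx=cx, cy=cy, w=w, h=h),
        class_probs=one_hot(category) if class_probs is None else np.asarray(class_probs, float),
        confidence=confidence,
        appearance=appearance,
    )


def make_frame(frame_index: int, detections, frame_size=(1044, 1392)) -> FrameDetections:
    return FrameDetections(
        frame_index=frame_index,
        timestamp=float(frame_index),
        detections=list(detections),
        frame_size=frame_size,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    """A small random but valid detection sequence (some frames empty)."""
    frames = []
    for i in range(12):
        n = int(rng.integers(0, 4))
        dets = [
            make_detection(
                cx=float(rng.uniform(100, 1200)),
                cy=float(rng.uniform(100, 900)),
                w=float(rng.uniform(50, 200)),
                h=float(rng.uniform(100, 400)),
                category=Category(int(rng.integers(0, 3))),
                confidence=float(rng.uniform(0.1, 1.0)),
                class_probs=rng.dirichlet(np.ones(3)),
                appearance=unit_vector(rng),
            )
            for _ in range(n)
        ]
        frames.append(make_frame(i, dets))
    return frames
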