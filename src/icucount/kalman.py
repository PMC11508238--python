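"""Constant-velocity Kalman filter over box geometry.

State is the 8-vector (cx, cy, a, h, vcx, vcy, va, vh) where a = w/h is
the aspect ratio; the measurement is the first four components.  Process
and measurement noise follow the convention of appearance-based online
trackers: standard deviations proportional to the box height, so large
(near-camera) boxes are allowed to move more in pixel terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BoundingBox

STATE_DIM = 8
MEAS_DIM = 4

#: Noise scale relative to box height.
STD_WEIGHT_POSITION = 1.0 / 20.0
STD_WEIGHT_VELOCITY = 1.0 / 160.0

_F = np.eye(STATE_DIM)
_F[:MEAS_DIM, MEAS_DIM:] = np.eye(MEAS_DIM)  # x' = x + v
_H = np.eye(MEAS_DIM, STATE_DIM)


@dataclass(frozen=True)
class KalmanState:
    """Filter mean and covariance for one trajectory."""

    mean: np.ndarray  # (8,)
    covariance: np.ndarray  # (8, 8)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (STATE_DIM,) or cov.shape != (STATE_DIM, STATE_DIM):
            raise ValueError("KalmanState must hold an 8-vector mean and 8x8 covariance")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def box(self) -> BoundingBox:
        cx, cy, a, h = self.mean[:MEAS_DIM]
        return BoundingBox(cx=float(cx), cy=float(cy), w=float(a * h), h=float(h))


def _measurement(box: BoundingBox) -> np.ndarray:
    return np.array([box.cx, box.cy, box.aspect, box.h], dtype=float)


def kalman_init(box: BoundingBox) -> KalmanState:
    """Start a filter at a measured box with zero velocity and broad
    velocity uncertainty."""
    mean = np.zeros(STATE_DIM)
    mean[:MEAS_DIM] = _measurement(box)
    h = box.h
    std = np.array(
        [
            2 * STD_WEIGHT_POSITION * h,
            2 * STD_WEIGHT_POSITION * h,
            1e-2,
            2 * STD_WEIGHT_POSITION * h,
            10 * STD_WEIGHT_VELOCITY * h,
            10 * STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * STD_WEIGHT_VELOCITY * h,
        ]
    )
    return KalmanState(mean=mean, covariance=np.diag(std**2))


def _process_noise(h: float) -> np.ndarray:
    std = np.array(
        [
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_POSITION * h,
            1e-2,
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_VELOCITY * h,
            STD_WEIGHT_VELOCITY * h,
            1e-5,
            STD_WEIGHT_VELOCITY * h,
        ]
    )
    return np.diag(std**2)


def _measurement_noise(h: float) -> np.ndarray:
    std = np.array(
        [
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_POSITION * h,
            1e-1,
            STD_WEIGHT_POSITION * h,
        ]
    )
    return np.diag(std**2)


def kalman_predict(state: KalmanState, process_noise: np.ndarray | None = None) -> KalmanState:
    """Propagate one frame under the constant-velocity model."""
    if process_noise is None:
        process_noise = _process_noise(float(state.mean[3]))
    mean = _F @ state.mean
    cov = _F @ state.covariance @ _F.T + process_noise
    return KalmanState(mean=mean, covariance=(cov + cov.T) / 2.0)


def kalman_update(
    state: KalmanState, box: BoundingBox, measurement_noise: np.ndarray | None = None
) -> KalmanState:
    """Standard measurement update on (cx, cy, a, h)."""
    if box.h <= 0:
        raise ValueError("measurement height must be positive")
    if measurement_noise is None:
        measurement_noise = _measurement_noise(box.h)
    z = _measurement(box)
    S = _H @ state.covariance @ _H.T + measurement_noise
    K = state.covariance @ _H.T @ np.linalg.inv(S)
    innovation = z - _H @ state.mean
    mean = state.mean + K @ innovation
    # Joseph form keeps the covariance symmetric PSD even with a zero
    # measurement-noise limit.
    IKH = np.eye(STATE_DIM) - K @ _H
    cov = IKH @ state.covariance @ IKH.T + K @ measurement_noise @ K.T
    if mean[3] <= 0:
        raise ValueError("posterior height became nonpositive")
    return KalmanState(mean=mean, covariance=(cov + cov.T) / 2.0)
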