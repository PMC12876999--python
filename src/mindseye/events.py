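"""Velocity/acceleration-threshold fixation detection from raw gaze samples.

A sample belongs to a fixation when the pupil is valid and both the gaze
velocity and the magnitude of its acceleration stay strictly below the
thresholds (defaults 30 deg/s and 8000 deg/s^2).  Velocity is estimated by
central differences of the angular gaze position after moving-average
smoothing; acceleration by central differences of the velocity components.
Maximal runs of fixational samples lasting at least ``min_fixation_ms``
become fixations, positioned at the centroid of the run's raw samples.

This is a documented stand-in for proprietary tracker parsers, which do
not publish their internal smoothing; thresholds are the standard
saccade-detection defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, InputError
from .io import Fixation, RawSampleTrack, ScreenGeometry

# Relative guard so a velocity sitting numerically on the threshold is
# classified as saccadic (the comparison is strict by definition).
_TIE_GUARD = 1e-9


@dataclass(frozen=True)
class DetectionConfig:
    velocity_threshold: float = 30.0     # deg/s
    acceleration_threshold: float = 8000.0  # deg/s^2
    min_fixation_ms: float = 40.0
    smoothing_window: int = 5            # samples, odd

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.acceleration_threshold <= 0:
            raise InputError("thresholds must be positive")
        if self.min_fixation_ms <= 0:
            raise InputError("min_fixation_ms must be positive")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise InputError("smoothing_window must be odd and >= 3")


def _px_to_deg_signed(offset_px: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Signed angular position of screen offsets from the display centre.

    Vectorized twin of :func:`mindseye.io.px_to_deg` applied to signed
    extents.
    """
    half_chord_mm = np.abs(offset_px) * geometry.pixel_pitch_mm / 2.0
    ang = np.degrees(2.0 * np.arctan(half_chord_mm / geometry.viewing_distance_mm))
    return np.sign(offset_px) * ang


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < window:
        return x
    pad = window // 2
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _central_diff(x: np.ndarray, dt_s: float) -> np.ndarray:
    """Central differences, one-sided at the boundaries."""
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt_s)
    d[0] = (x[1] - x[0]) / dt_s
    d[-1] = (x[-1] - x[-2]) / dt_s
    return d


def detect_fixations(track: RawSampleTrack, geometry: ScreenGeometry,
                     config: DetectionConfig | None = None) -> list[Fixation]:
    """Detect fixations in a raw sample track.

    Returns a time-ordered, non-overlapping list of fixations.  Invalid
    (blink) samples always break fixation runs.
    """
    config = config or DetectionConfig()
    n = len(track)
    if n < 3:
        raise InputError(f"need at least 3 samples, got {n}")
    dts = np.diff(track.times_ms)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > 0.1 * dt):
        raise DataError("sampling interval varies by more than 10%")
    dt_s = dt / 1000.0

    cx, cy = geometry.width_px / 2.0, geometry.height_px / 2.0
    ax = _px_to_deg_signed(track.x_px - cx, geometry)
    ay = _px_to_deg_signed(track.y_px - cy, geometry)
    ax = _smooth(ax, config.smoothing_window)
    ay = _smooth(ay, config.smoothing_window)

    vx = _central_diff(ax, dt_s)
    vy = _central_diff(ay, dt_s)
    speed = np.hypot(vx, vy)
    acc = np.hypot(_central_diff(vx, dt_s), _central_diff(vy, dt_s))

    v_cut = config.velocity_threshold * (1.0 - _TIE_GUARD)
    a_cut = config.acceleration_threshold * (1.0 - _TIE_GUARD)
    fixational = track.valid & (speed < v_cut) & (acc < a_cut)

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        if not fixational[i]:
            i += 1
            continue
        j = i
        while j < n and fixational[j]:
            j += 1
        span_ms = (j - i) * dt
        if span_ms >= config.min_fixation_ms:
            fixations.append(
                Fixation(
                    onset_ms=float(track.times_ms[i]),
                    duration_ms=span_ms,
                    x_px=float(np.mean(track.x_px[i:j])),
                    y_px=float(np.mean(track.y_px[i:j])),
                )
            )
        i = j
    return fixations
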