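"""Speed and acceleration series from a keypoint track.

Speed is the frame-to-frame Euclidean displacement in pixels, attributed to
the later frame (index 0 repeats index 1's value so the series stays the
same length as the track, which keeps elementwise products simple in the
segmentation stage). Both speed and its gradient are smoothed with a
third-order Savitzky-Golay filter, window 59 frames, with polynomial edge
interpolation to avoid wrap-around artifacts near movement onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

DEFAULT_WINDOW = 59
DEFAULT_ORDER = 3


def compute_speed(x, y=None) -> np.ndarray:
    """Per-frame displacement magnitude in px/frame.

    Accepts either a :class:`~pickplace.pose_io.KeypointTrack`-like object
    (anything with ``.x`` and ``.y``) or two coordinate arrays.
    """
    if y is None:
        x, y = x.x, x.y
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 frames to compute speed")
    step = np.hypot(np.diff(x), np.diff(y))
    return np.concatenate([[step[0]], step])


def smooth_series(series, order: int = DEFAULT_ORDER, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Savitzky-Golay polynomial smoothing; output length equals input length."""
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    if series.size < window:
        raise ValueError(
            f"series of length {series.size} is shorter than the window {window}")
    return savgol_filter(series, window, order, mode="interp")


def compute_acceleration(smoothed_speed, order: int = DEFAULT_ORDER,
                         window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Central-difference gradient of smoothed speed, smoothed again.

    Units: px/frame^2 when fed a px/frame speed series.
    """
    grad = np.gradient(np.asarray(smoothed_speed, dtype=float))
    return smooth_series(grad, order=order, window=window)


@dataclass
class KinematicSeries:
    """Raw speed, smoothed speed, and smoothed acceleration for one track.

    Native units are px/frame (and px/frame^2); ``speed_cm_s`` applies the
    track calibration.
    """

    speed: np.ndarray
    smoothed_speed: np.ndarray
    acceleration: np.ndarray
    fps: float
    pixel_scale: float
    smoothing_order: int = DEFAULT_ORDER
    smoothing_window: int = DEFAULT_WINDOW

    @classmethod
    def from_track(cls, track, order: int = DEFAULT_ORDER,
                   window: int = DEFAULT_WINDOW) -> "KinematicSeries":
        speed = compute_speed(track)
        smoothed = smooth_series(speed, order=order, window=window)
        accel = compute_acceleration(smoothed, order=order, window=window)
        return cls(speed=speed, smoothed_speed=smoothed, acceleration=accel,
                   fps=track.fps, pixel_scale=track.pixel_scale,
                   smoothing_order=order, smoothing_window=window)

    def to_cm_s(self, series_px_frame) -> np.ndarray:
        """Convert a px/frame series to cm/s using the track calibration."""
        return np.asarray(series_px_frame) * self.pixel_scale * self.fps

    @property
    def smoothed_speed_cm_s(self) -> np.ndarray:
        return self.to_cm_s(self.smoothed_speed)

    @property
    def acceleration_cm_s_frame(self) -> np.ndarray:
        """Smoothed acceleration in cm/s per frame."""
        return self.to_cm_s(self.acceleration)
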