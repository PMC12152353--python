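"""Keypoint track I/O, confidence-based repair, and unit calibration.

Tracks are per-frame (x, y, likelihood) series for one joint, as produced
by markerless pose estimators from top-down video. Positions are in
pixels; the likelihood score in [0, 1] is the estimator's confidence.
Files are stored as HDF5 (one group per joint, datasets ``x``, ``y``,
``likelihood``, calibration in root attributes) or as plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from types import SimpleNamespace

import h5py
import numpy as np
import pandas as pd

DEFAULT_JOINT = "index_mcp"  # metacarpophalangeal joint of the right index finger


class TrackFormatError(ValueError):
    """File cannot be parsed as a keypoint track."""


class JointNotFoundError(KeyError):
    """Requested joint is not present in the file."""


class UnrecoverableTrackError(ValueError):
    """No frame reaches the confidence threshold; interpolation impossible."""


@dataclass
class KeypointTrack:
    """Per-frame pixel positions and confidence for a single joint."""

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = 200.0
    pixel_scale: float = 0.042  # cm per pixel
    joint_name: str = DEFAULT_JOINT

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValueError("x, y and likelihood must have equal length")
        if self.x.ndim != 1:
            raise ValueError("track series must be one-dimensional")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.likelihood.size and (
            self.likelihood.min() < 0 or self.likelihood.max() > 1
        ):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.x.size


def save_tracks_hdf5(path: str | Path, tracks: dict[str, KeypointTrack] | KeypointTrack) -> None:
    """Write one or more joint tracks to an HDF5 file."""
    if isinstance(tracks, KeypointTrack):
        tracks = {tracks.joint_name: tracks}
    with h5py.File(path, "w") as f:
        for joint, tr in tracks.items():
            g = f.create_group(joint)
            g.create_dataset("x", data=tr.x)
            g.create_dataset("y", data=tr.y)
            g.create_dataset("likelihood", data=tr.likelihood)
        first = next(iter(tracks.values()))
        f.attrs["fps"] = first.fps
        f.attrs["pixel_scale"] = first.pixel_scale


def save_track_csv(path: str | Path, track: KeypointTrack) -> None:
    df = pd.DataFrame({"frame": np.arange(track.n_frames),
                       "x": track.x, "y": track.y,
                       "likelihood": track.likelihood})
    df.to_csv(path, index=False)


def load_keypoint_track(path: str | Path, joint: str = DEFAULT_JOINT,
                        fps: float = 200.0, pixel_scale: float = 0.042) -> KeypointTrack:
    """Load a single joint's track from HDF5 or CSV.

    For HDF5, calibration comes from file attributes; the ``fps`` and
    ``pixel_scale`` arguments are only used for CSV files, which do not
    carry calibration.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        try:
            f = h5py.File(path, "r")
        except OSError as exc:
            raise TrackFormatError(f"cannot read HDF5 file {path}: {exc}") from exc
        with f:
            if joint not in f:
                raise JointNotFoundError(
                    f"joint {joint!r} not in {path} (has {sorted(f.keys())})")
            g = f[joint]
            try:
                x, y, lik = g["x"][:], g["y"][:], g["likelihood"][:]
            except KeyError as exc:
                raise TrackFormatError(f"joint group {joint!r} lacks {exc}") from exc
            return KeypointTrack(x, y, lik,
                                 fps=float(f.attrs.get("fps", fps)),
                                 pixel_scale=float(f.attrs.get("pixel_scale", pixel_scale)),
                                 joint_name=joint)
    if path.suffix == ".csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            raise TrackFormatError(f"cannot parse CSV file {path}: {exc}") from exc
        for col in ("x", "y", "likelihood"):
            if col not in df.columns:
                raise TrackFormatError(f"CSV {path} lacks column {col!r}")
        return KeypointTrack(df["x"].to_numpy(), df["y"].to_numpy(),
                             df["likelihood"].to_numpy(), fps=fps,
                             pixel_scale=pixel_scale, joint_name=joint)
    raise TrackFormatError(f"unrecognized track file extension: {path.suffix!r}")


def interpolate_low_confidence(track: KeypointTrack, threshold: float = 0.7) -> KeypointTrack:
    """Linearly interpolate positions where the likelihood is below threshold.

    Confident frames are untouched. Runs of unconfident frames at the track
    boundaries are filled with the nearest confident value (no
    extrapolation). Idempotent: a second pass changes nothing.
    """
    good = track.likelihood >= threshold
    if not good.any():
        raise UnrecoverableTrackError(
            f"no frame reaches likelihood {threshold}; track is unusable")
    if good.all():
        return replace(track)
    idx = np.arange(track.n_frames)
    gi = idx[good]
    # np.interp holds the first/last confident value constant at the edges
    x = np.interp(idx, gi, track.x[good])
    y = np.interp(idx, gi, track.y[good])
    return replace(track, x=x, y=y)


def to_physical(track: KeypointTrack) -> SimpleNamespace:
    """Convert a pixel/frame track to centimeters and milliseconds.

    Returns a namespace with ``x_cm``, ``y_cm`` (positions scaled by
    ``pixel_scale``) and ``t_ms`` (frame i at i * 1000 / fps).
    """
    if not track.pixel_scale or track.pixel_scale <= 0:
        raise ValueError("track has no valid pixel_scale calibration")
    if not track.fps or track.fps <= 0:
        raise ValueError("track has no valid fps calibration")
    t_ms = np.arange(track.n_frames) * (1000.0 / track.fps)
    return SimpleNamespace(x_cm=track.x * track.pixel_scale,
                           y_cm=track.y * track.pixel_scale,
                           t_ms=t_ms, fps=track.fps)


def frames_to_ms(n_frames, fps: float = 200.0):
    """Duration of ``n_frames`` frames in milliseconds (50 frames @ 200 fps = 250 ms)."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    return np.asarray(n_frames, dtype=float) * 1000.0 / fps
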