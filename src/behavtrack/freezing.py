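"""Freezing detection from calibrated changed-pixel motion counts.

Motion on frame ``t`` is the number of pixels whose Gaussian-filtered
grayscale value changes by strictly more than the motion threshold (MT)
relative to frame ``t - 1``. Every video shows small pixel fluctuations even
with a static scene, so MT is calibrated from a short recording of the empty
arena: pool all filtered frame-to-frame absolute differences and take a high
percentile of that null distribution (by default twice the 99.99th
percentile). Freezing — the absence of movement barring respiration — is
declared whenever motion stays strictly below the freezing threshold (FT)
for at least a minimum duration.

Conventions: the first analyzed frame has motion 0 (no prior frame) and may
join a freezing run; comparisons are strict on both thresholds; Gaussian
filtering uses reflect boundary handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .video_io import FrameRange, FrameStream

logger = logging.getLogger(__name__)

__all__ = [
    "FreezeParams",
    "CalibrationReport",
    "MotionTrace",
    "FreezeTrace",
    "calibrate_motion_threshold",
    "measure_motion",
    "detect_freezing",
    "percent_freezing",
    "min_duration_frames",
    "measure_session",
]

DEFAULT_SIGMA = 1.0
DEFAULT_CALIB_PERCENTILE = 99.99
DEFAULT_CALIB_MULTIPLIER = 2.0


@dataclass
class FreezeParams:
    """Parameters of the freeze-analysis pipeline.

    sigma : Gaussian filter standard deviation in pixels (default 1).
    motion_threshold : MT, grayscale-change cutoff; a pixel counts as
        changed when its filtered change is strictly greater.
    freeze_threshold : FT, changed-pixel count below which (strictly) a
        frame is a freezing candidate.
    min_freeze_frames : minimum length of a candidate run to count as
        freezing, in frames (use :func:`min_duration_frames` to convert a
        duration in seconds via the video fps).
    """

    motion_threshold: float
    freeze_threshold: float
    min_freeze_frames: int = 1
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0 (0 disables smoothing)")
        if self.motion_threshold < 0:
            raise ValueError("motion_threshold must be >= 0")
        if self.freeze_threshold < 0:
            raise ValueError("freeze_threshold must be >= 0")
        if self.min_freeze_frames < 1:
            raise ValueError("min_freeze_frames must be >= 1")


def min_duration_frames(seconds: float, fps: float) -> int:
    """Convert a minimum freeze duration in seconds to frames (nearest
    integer, floor 1)."""
    return max(1, int(round(seconds * fps)))


@dataclass
class CalibrationReport:
    """Null-distribution summary from an empty-arena video."""

    suggested_mt: float
    percentile_used: float
    multiplier: float
    percentile_value: float
    null_distribution: np.ndarray
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray


@dataclass
class MotionTrace:
    """Per-frame changed-pixel counts (`frame`, `motion` arrays)."""

    frames: np.ndarray
    motion: np.ndarray
    n_pixels: int
    fps: float = 30.0
    file: Optional[str] = None


@dataclass
class FreezeTrace:
    """Per-frame freezing flags aligned with a :class:`MotionTrace`."""

    frames: np.ndarray
    freezing: np.ndarray  # boolean
    min_freeze_frames: int

    def as_percent_column(self) -> np.ndarray:
        """Flags encoded 0/100 so that bin means are percentages."""
        return self.freezing.astype(float) * 100.0


def _filtered_frames(stream: FrameStream, sigma: float):
    for idx, frame in stream:
        if sigma > 0:
            frame = ndimage.gaussian_filter(frame, sigma, mode="reflect")
        yield idx, frame


def calibrate_motion_threshold(
    empty_stream: FrameStream,
    percentile: float = DEFAULT_CALIB_PERCENTILE,
    multiplier: float = DEFAULT_CALIB_MULTIPLIER,
    sigma: float = DEFAULT_SIGMA,
) -> CalibrationReport:
    """Suggest a motion threshold from an empty-arena recording.

    Gaussian-filters each frame, pools the absolute pixel differences over
    all consecutive frame pairs, and suggests
    ``multiplier x (percentile of the pooled values)``.
    """
    if len(empty_stream) < 2:
        raise ValueError("calibration requires a video with at least 2 frames")
    pooled: list[np.ndarray] = []
    prev = None
    for _, frame in _filtered_frames(empty_stream, sigma):
        if prev is not None:
            pooled.append(np.abs(frame - prev).ravel())
        prev = frame
    values = np.concatenate(pooled)
    pct_value = float(np.percentile(values, percentile))
    suggested = multiplier * pct_value
    if suggested == 0:
        logger.warning(
            "empty-arena video is perfectly static; suggested MT is 0 — "
            "any real sensor noise will register as motion"
        )
    counts, edges = np.histogram(values, bins=100)
    return CalibrationReport(
        suggested_mt=suggested,
        percentile_used=percentile,
        multiplier=multiplier,
        percentile_value=pct_value,
        null_distribution=values,
        histogram_counts=counts,
        histogram_edges=edges,
    )


def measure_motion(
    stream: FrameStream, motion_threshold: float, sigma: float = DEFAULT_SIGMA
) -> MotionTrace:
    """Count, per frame, pixels whose filtered change from the prior frame
    strictly exceeds the motion threshold (first frame: 0 by convention)."""
    if motion_threshold < 0:
        raise ValueError("motion_threshold must be >= 0")
    if len(stream) < 2:
        raise ValueError("motion measurement requires at least 2 frames")
    frames: list[int] = []
    motion: list[int] = []
    prev = None
    for idx, frame in _filtered_frames(stream, sigma):
        if prev is None:
            motion.append(0)
        else:
            motion.append(int(np.count_nonzero(np.abs(frame - prev) > motion_threshold)))
        frames.append(idx)
        prev = frame
    path = stream.meta.path
    return MotionTrace(
        frames=np.asarray(frames),
        motion=np.asarray(motion),
        n_pixels=stream.meta.height * stream.meta.width,
        fps=stream.meta.fps,
        file=str(path) if path else None,
    )


def detect_freezing(
    trace: MotionTrace | np.ndarray,
    freeze_threshold: float,
    min_freeze_frames: int = 1,
) -> FreezeTrace:
    """Flag freezing frames: maximal runs of motion strictly below the
    freezing threshold lasting at least ``min_freeze_frames``."""
    if min_freeze_frames < 1:
        raise ValueError("min_freeze_frames must be >= 1")
    if isinstance(trace, MotionTrace):
        motion, frames = trace.motion, trace.frames
    else:
        motion = np.asarray(trace)
        frames = np.arange(motion.size)
    candidate = motion < freeze_threshold
    freezing = np.zeros(motion.size, dtype=bool)
    # boundaries of maximal candidate runs
    padded = np.concatenate(([False], candidate, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    for s, e in zip(starts, ends):
        if e - s >= min_freeze_frames:
            freezing[s:e] = True
    return FreezeTrace(
        frames=frames, freezing=freezing, min_freeze_frames=min_freeze_frames
    )


def percent_freezing(
    trace: FreezeTrace, frame_range: Optional[FrameRange] = None
) -> float:
    """Percentage of analyzed frames flagged as freezing, optionally over a
    half-open sub-range of frame indices."""
    flags = trace.freezing
    if frame_range is not None:
        mask = (trace.frames >= frame_range.start) & (trace.frames < frame_range.end)
        flags = flags[mask]
    if flags.size == 0:
        raise ValueError("empty frame range for percent_freezing")
    return 100.0 * float(np.count_nonzero(flags)) / flags.size


def measure_session(stream: FrameStream, params: FreezeParams) -> pd.DataFrame:
    """Full freeze pipeline for one video: motion counting plus freezing
    classification, as a per-frame DataFrame (freezing encoded 0/100)."""
    trace = measure_motion(stream, params.motion_threshold, params.sigma)
    freeze = detect_freezing(trace, params.freeze_threshold, params.min_freeze_frames)
    path = stream.meta.path
    return pd.DataFrame(
        {
            "file": str(path) if path else "",
            "frame": trace.frames,
            "motion": trace.motion,
            "freezing": freeze.as_percent_column(),
        }
    )
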