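"""Center-of-mass location tracking by reference-frame differencing.

The tracker compares each frame against a reference image of the arena
without the animal, estimated as the pixel-wise median over a random sample
of session frames (the animal occupies any one pixel in well under half the
session, so the median recovers the background). Per-frame pixel differences
are optionally down-weighted outside a square window around the previous
position (weight ``1 - omega`` outside), then thresholded so that only
values strictly above a chosen percentile of the frame's differences
survive, and the intensity-weighted center of mass of the survivors gives
the animal's sub-pixel position. Euclidean steps between successive
positions yield per-frame distance, convertible to physical units via a
two-point scale calibration. Named polygonal regions of interest (ROIs) are
scored per frame from center-of-mass membership.

Because the percentile cutoff is relative to each frame's own difference
distribution, tracking is robust to global illumination changes (e.g. the
dark side of a light-dark box). The window weighting exists to suppress
transient interfering objects (a hand, a cable) far from the animal: their
down-weighted difference values fall below the relative cutoff and drop out
of the center of mass entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .video_io import FrameStream

logger = logging.getLogger(__name__)

__all__ = [
    "DiffMode",
    "LocationParams",
    "ReferenceFrame",
    "ScaleCalibration",
    "ROI",
    "TrackingResult",
    "make_reference",
    "frame_difference",
    "threshold_by_percentile",
    "apply_location_weight",
    "center_of_mass",
    "point_in_roi",
    "calibrate_scale",
    "track_session",
]

DIFF_MODES = ("absolute", "animal_lighter", "animal_darker")
DiffMode = str


@dataclass
class LocationParams:
    """Parameters of the location-tracking pipeline.

    Attributes
    ----------
    diff_mode
        ``"absolute"`` tracks regardless of contrast polarity;
        ``"animal_lighter"`` / ``"animal_darker"`` assume the animal is
        brighter / darker than the background.
    loc_thresh
        Percentile of each frame's difference values below which pixels are
        zeroed (strictly-greater survival). Default 99.
    use_window, window_size, window_weight
        Enable the prior-position weighting window, its square side length
        in pixels (odd), and the weight omega in [0, 1]: values outside the
        window are multiplied by ``1 - omega``.
    reference_sample_n
        Number of frames sampled (without replacement) for the median
        reference image. Default 100.
    rng_seed
        Seed for the reference-frame sampling, recorded in the reference
        provenance.
    binarize
        If True, surviving difference values are set to 1 before the center
        of mass (off by default: survivors keep their magnitudes).
    """

    diff_mode: DiffMode = "absolute"
    loc_thresh: float = 99.0
    use_window: bool = False
    window_size: int = 61
    window_weight: float = 0.9
    reference_sample_n: int = 100
    rng_seed: int = 0
    binarize: bool = False

    def __post_init__(self) -> None:
        if self.diff_mode not in DIFF_MODES:
            raise ValueError(f"diff_mode must be one of {DIFF_MODES}")
        if not (0 < self.loc_thresh < 100):
            raise ValueError("loc_thresh must lie in (0, 100)")
        if not (0 <= self.window_weight <= 1):
            raise ValueError("window_weight must lie in [0, 1]")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")
        if self.reference_sample_n < 1:
            raise ValueError("reference_sample_n must be >= 1")


@dataclass(frozen=True)
class ReferenceFrame:
    """Pixel-wise median background image with sampling provenance."""

    image: np.ndarray
    sample_indices: tuple[int, ...]
    source: str  # "same_video" | "external_video"

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-physical-unit conversion from two marked points."""

    point_a: tuple[float, float]
    point_b: tuple[float, float]
    true_distance: float
    unit_label: str
    factor: float  # units per pixel


@dataclass(frozen=True)
class ROI:
    """Named simple polygon in frame coordinates ((x, y) vertices)."""

    name: str
    vertices: tuple[tuple[float, float], ...]
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __init__(self, name: str, vertices: Sequence[Sequence[float]]):
        if len(vertices) < 3:
            raise ValueError(f"ROI {name!r}: a polygon needs >= 3 vertices")
        poly = Polygon([(float(x), float(y)) for x, y in vertices])
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"ROI {name!r}: degenerate or self-intersecting polygon")
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in vertices)
        )
        object.__setattr__(self, "_polygon", poly)


def point_in_roi(point: Sequence[float], roi: ROI) -> bool:
    """Polygon membership; points on the boundary count as inside."""
    return bool(roi._polygon.covers(Point(float(point[0]), float(point[1]))))


def calibrate_scale(
    point_a: Sequence[float],
    point_b: Sequence[float],
    true_distance: float,
    unit_label: str = "cm",
) -> ScaleCalibration:
    """Build a conversion factor (units per pixel) from two marked points
    a known physical distance apart."""
    ax, ay = (float(v) for v in point_a)
    bx, by = (float(v) for v in point_b)
    pixel_dist = math.hypot(bx - ax, by - ay)
    if pixel_dist == 0:
        raise ValueError("calibration points must be distinct")
    if true_distance <= 0:
        raise ValueError("true_distance must be > 0")
    return ScaleCalibration(
        point_a=(ax, ay),
        point_b=(bx, by),
        true_distance=float(true_distance),
        unit_label=unit_label,
        factor=float(true_distance) / pixel_dist,
    )


def make_reference(
    stream: FrameStream,
    params: Optional[LocationParams] = None,
    external_stream: Optional[FrameStream] = None,
) -> ReferenceFrame:
    """Estimate the arena background as a pixel-wise median image.

    Samples ``params.reference_sample_n`` frame indices uniformly without
    replacement (all frames if fewer exist), seeded by ``params.rng_seed``,
    and takes the per-pixel median over the sampled frames. If
    ``external_stream`` (an empty-arena video) is given, the median is
    computed over its frames instead; its dimensions must match.
    """
    params = params or LocationParams()
    src, source = (stream, "same_video")
    if external_stream is not None:
        if (external_stream.meta.height, external_stream.meta.width) != (
            stream.meta.height,
            stream.meta.width,
        ):
            raise ValueError(
                "external reference video dimensions "
                f"{external_stream.meta.height}x{external_stream.meta.width} do not "
                f"match the analyzed stream {stream.meta.height}x{stream.meta.width}"
            )
        src, source = external_stream, "external_video"

    fr = src.frame_range
    available = np.arange(fr.start, fr.end)
    n = min(params.reference_sample_n, available.size)
    rng = np.random.default_rng(params.rng_seed)
    chosen = np.sort(rng.choice(available, size=n, replace=False))
    wanted = set(int(i) for i in chosen)

    sampled = [frame for idx, frame in src if idx in wanted]
    if not sampled:
        raise ValueError("reference sampling collected no frames")
    image = np.median(np.stack(sampled), axis=0)
    return ReferenceFrame(
        image=image, sample_indices=tuple(int(i) for i in chosen), source=source
    )


def frame_difference(
    frame: np.ndarray, reference: ReferenceFrame | np.ndarray, diff_mode: DiffMode
) -> np.ndarray:
    """Non-negative pixel difference between a frame and the reference."""
    ref = reference.image if isinstance(reference, ReferenceFrame) else reference
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != ref.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match reference {ref.shape}"
        )
    if diff_mode == "absolute":
        return np.abs(frame - ref)
    if diff_mode == "animal_lighter":
        return np.maximum(frame - ref, 0.0)
    if diff_mode == "animal_darker":
        return np.maximum(ref - frame, 0.0)
    raise ValueError(f"diff_mode must be one of {DIFF_MODES}")


def threshold_by_percentile(diff: np.ndarray, loc_thresh: float) -> np.ndarray:
    """Zero all entries not strictly above the loc_thresh-th percentile.

    The cutoff is the linear-interpolation percentile of *all* entries of
    the frame's difference image; survivors retain their magnitudes. Because
    the cutoff is relative, the operation is invariant to rescaling the
    whole image (global illumination changes).
    """
    cutoff = np.percentile(diff, loc_thresh)
    return np.where(diff > cutoff, diff, 0.0)


def apply_location_weight(
    diff: np.ndarray,
    prior_com: Sequence[float],
    window_size: int,
    window_weight: float,
) -> np.ndarray:
    """Multiply difference values outside a square window around the prior
    position by ``1 - window_weight``; the window is clipped at the edges."""
    h, w = diff.shape
    cx = int(round(prior_com[0]))
    cy = int(round(prior_com[1]))
    half = window_size // 2
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    out = diff * (1.0 - window_weight)
    out[y0:y1, x0:x1] = diff[y0:y1, x0:x1]
    return out


def center_of_mass(
    weighted_diff: np.ndarray, fallback: Sequence[float]
) -> tuple[float, float]:
    """Intensity-weighted mean pixel coordinate, ``(x, y)`` = (col, row).

    If the image is all-zero (nothing above threshold) the fallback
    position is returned and a warning logged.
    """
    total = weighted_diff.sum()
    if total <= 0:
        logger.warning(
            "all-zero difference image; falling back to position (%.1f, %.1f)",
            fallback[0],
            fallback[1],
        )
        return float(fallback[0]), float(fallback[1])
    h, w = weighted_diff.shape
    x = float(weighted_diff.sum(axis=0) @ np.arange(w)) / total
    y = float(weighted_diff.sum(axis=1) @ np.arange(h)) / total
    return x, y


@dataclass
class TrackingResult:
    """Per-frame tracking output.

    ``data`` has one row per analyzed frame with columns ``frame``, ``x``,
    ``y``, ``distance_px``, optionally ``distance_<unit>``, and one 0/1
    column per ROI name.
    """

    data: pd.DataFrame
    reference: ReferenceFrame
    params: LocationParams
    roi_names: tuple[str, ...] = ()
    calibration: Optional[ScaleCalibration] = None
    file: Optional[str] = None
    fps: float = 30.0

    @property
    def total_distance_px(self) -> float:
        return float(self.data["distance_px"].sum())

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "file", self.file or "")
        df.to_csv(path, index=False)


def track_session(
    stream: FrameStream,
    reference: ReferenceFrame,
    params: Optional[LocationParams] = None,
    rois: Sequence[ROI] = (),
    cal: Optional[ScaleCalibration] = None,
) -> TrackingResult:
    """Track the animal's center of mass across a session.

    Per frame: difference from the reference, prior-position window
    weighting (when enabled and a prior position exists; never on the first
    analyzed frame), relative percentile thresholding, then the weighted
    center of mass. Distances are Euclidean steps between successive
    positions (0 on the first frame); ROI membership is scored per frame.
    """
    params = params or LocationParams()
    ref = reference.image
    if (stream.meta.height, stream.meta.width) != ref.shape:
        raise ValueError(
            f"reference shape {ref.shape} does not match stream "
            f"{stream.meta.height}x{stream.meta.width}"
        )
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        raise ValueError("ROI names must be unique")

    h, w = ref.shape
    rows: list[dict] = []
    prior: Optional[tuple[float, float]] = None
    for idx, frame in stream:
        diff = frame_difference(frame, ref, params.diff_mode)
        if params.use_window and prior is not None:
            diff = apply_location_weight(
                diff, prior, params.window_size, params.window_weight
            )
        diff = threshold_by_percentile(diff, params.loc_thresh)
        if params.binarize:
            diff = (diff > 0).astype(np.float64)
        fallback = prior if prior is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
        pos = center_of_mass(diff, fallback)
        step = 0.0 if prior is None else math.hypot(pos[0] - prior[0], pos[1] - prior[1])
        row = {"frame": idx, "x": pos[0], "y": pos[1], "distance_px": step}
        for roi in rois:
            row[roi.name] = int(point_in_roi(pos, roi))
        rows.append(row)
        prior = pos

    df = pd.DataFrame(rows)
    if cal is not None:
        df.insert(
            df.columns.get_loc("distance_px") + 1,
            f"distance_{cal.unit_label}",
            df["distance_px"] * cal.factor,
        )
    path = stream.meta.path
    return TrackingResult(
        data=df,
        reference=reference,
        params=params,
        roi_names=tuple(names),
        calibration=cal,
        file=str(path) if path else None,
        fps=stream.meta.fps,
    )
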