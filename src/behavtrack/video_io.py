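"""Streaming grayscale frame access to behavior videos.

Frames are decoded lazily, one at a time, so memory use is independent of
video length. All downstream analysis consumes a :class:`FrameStream`, which
applies (in order) frame-range restriction, rectangular cropping, and optional
spatial downsampling.

Coordinate conventions used throughout the package:

* 0-based indices; ``x`` is the column, ``y`` is the row.
* Crop regions and frame ranges are half-open intervals.
* Grayscale values lie in ``[0, 255]`` as floats.

On-disk fixtures are written as lossless multipage TIFF (frames-per-second
stored in the TIFF metadata), so decoding is bit-exact. Other containers are
decoded through whatever imageio plugins are installed; an unsupported or
corrupt file raises :class:`VideoDecodeError` naming the path.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "VideoMeta",
    "CropRegion",
    "FrameRange",
    "FrameStream",
    "VideoDecodeError",
    "open_video",
    "probe_video",
    "array_stream",
    "write_video",
]

#: ITU-R BT.601 luma weights, used when a source decodes to RGB(A).
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_FPS = 30.0


class VideoDecodeError(RuntimeError):
    """Raised when a file cannot be opened or decoded as video."""


@dataclass(frozen=True)
class VideoMeta:
    """Descriptive metadata for a frame stream (post-crop/downsample)."""

    path: Optional[Path]
    fps: float
    frame_count: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.frame_count < 1:
            raise ValueError(f"frame_count must be >= 1, got {self.frame_count}")
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be >= 1 pixel")


@dataclass(frozen=True)
class CropRegion:
    """Rectangular crop, top-left inclusive, bottom-right exclusive."""

    x0: int
    y0: int
    x1: int
    y1: int

    def validate(self, height: int, width: int) -> None:
        if not (0 <= self.x0 < self.x1 <= width):
            raise ValueError(
                f"crop x-range [{self.x0}, {self.x1}) invalid for width {width}"
            )
        if not (0 <= self.y0 < self.y1 <= height):
            raise ValueError(
                f"crop y-range [{self.y0}, {self.y1}) invalid for height {height}"
            )

    def apply(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y0 : self.y1, self.x0 : self.x1]

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def width(self) -> int:
        return self.x1 - self.x0


@dataclass(frozen=True)
class FrameRange:
    """Half-open range of 0-based frame indices ``[start, end)``."""

    start: int
    end: int

    def validate(self, frame_count: int) -> None:
        if not (0 <= self.start < self.end <= frame_count):
            raise ValueError(
                f"frame range [{self.start}, {self.end}) invalid for a "
                f"{frame_count}-frame video"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _to_gray(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return arr.astype(np.float64, copy=False)


class _Source:
    """Backend adapter: native metadata plus a lazy full-frame iterator."""

    path: Optional[Path] = None
    fps: float = DEFAULT_FPS
    frame_count: int = 0
    height: int = 0
    width: int = 0

    def iter_raw(self) -> Iterator[np.ndarray]:  # pragma: no cover - interface
        raise NotImplementedError


class _ArraySource(_Source):
    def __init__(self, stack: np.ndarray, fps: float = DEFAULT_FPS):
        stack = np.asarray(stack)
        if stack.ndim not in (3, 4):
            raise ValueError("expected a (frames, height, width[, channels]) stack")
        self.path = None
        self.fps = float(fps)
        self.frame_count = int(stack.shape[0])
        self.height = int(stack.shape[1])
        self.width = int(stack.shape[2])
        self._stack = stack

    def iter_raw(self) -> Iterator[np.ndarray]:
        for frame in self._stack:
            yield _to_gray(frame)


class _TiffSource(_Source):
    def __init__(self, path: Path):
        import tifffile

        self.path = path
        try:
            with tifffile.TiffFile(path) as tif:
                series = tif.series[0]
                shape = series.shape
                self.fps = _tiff_fps(tif)
        except Exception as exc:  # pragma: no cover - backend specific
            raise VideoDecodeError(f"cannot decode TIFF video {path}: {exc}") from exc
        if len(shape) == 2:
            self.frame_count = 1
            self.height, self.width = (int(s) for s in shape)
        else:
            self.frame_count = int(shape[0])
            self.height, self.width = int(shape[-2]), int(shape[-1])

    def iter_raw(self) -> Iterator[np.ndarray]:
        import tifffile

        with tifffile.TiffFile(self.path) as tif:
            for page in tif.series[0].pages:
                yield _to_gray(page.asarray())


def _tiff_fps(tif) -> float:
    meta = tif.shaped_metadata
    if meta:
        fps = meta[0].get("fps")
        if fps:
            return float(fps)
    return DEFAULT_FPS


class _ImageIOSource(_Source):
    """Fallback for whatever containers the installed imageio plugins decode."""

    def __init__(self, path: Path):
        import imageio.v3 as iio

        self.path = path
        try:
            props = iio.improps(path, index=...)
            meta = iio.immeta(path, exclude_applied=False)
        except Exception as exc:
            raise VideoDecodeError(f"cannot decode video {path}: {exc}") from exc
        shape = props.shape
        if len(shape) == 2:
            self.frame_count, (self.height, self.width) = 1, shape
        else:
            self.frame_count = int(shape[0])
            self.height, self.width = int(shape[1]), int(shape[2])
        self.fps = float(meta.get("fps", DEFAULT_FPS) or DEFAULT_FPS)

    def iter_raw(self) -> Iterator[np.ndarray]:
        import imageio.v3 as iio

        for frame in iio.imiter(self.path):
            yield _to_gray(frame)


class FrameStream:
    """Lazy, re-iterable sequence of processed grayscale frames.

    Iterating yields ``(frame_index, frame)`` pairs where ``frame_index`` is
    the 0-based index in the *source* video and ``frame`` is a float64
    ``(height, width)`` array. Two passes over the same stream yield identical
    pixels. If the backend stops early (corrupt trailing frames), iteration
    ends at the last decodable frame and a warning records the mismatch.
    """

    def __init__(
        self,
        source: _Source,
        crop: Optional[CropRegion] = None,
        frame_range: Optional[FrameRange] = None,
        downsample_factor: Optional[float] = None,
    ):
        if crop is not None:
            crop.validate(source.height, source.width)
        if frame_range is not None:
            frame_range.validate(source.frame_count)
        else:
            frame_range = FrameRange(0, source.frame_count)
        if downsample_factor is not None and downsample_factor <= 0:
            raise ValueError("downsample_factor must be positive")

        self._source = source
        self.crop = crop
        self.frame_range = frame_range
        self.downsample_factor = downsample_factor

        h = crop.height if crop else source.height
        w = crop.width if crop else source.width
        if downsample_factor:
            h = max(1, int(round(h / downsample_factor)))
            w = max(1, int(round(w / downsample_factor)))
        self.meta = VideoMeta(
            path=source.path,
            fps=source.fps,
            frame_count=len(frame_range),
            height=h,
            width=w,
        )

    def _process(self, frame: np.ndarray) -> np.ndarray:
        if self.crop is not None:
            frame = self.crop.apply(frame)
        if self.downsample_factor:
            zoom = (
                self.meta.height / frame.shape[0],
                self.meta.width / frame.shape[1],
            )
            frame = ndimage.zoom(frame, zoom, order=1, mode="nearest")
        return frame

    def __iter__(self) -> Iterator[tuple[int, np.ndarray]]:
        start, end = self.frame_range.start, self.frame_range.end
        yielded = 0
        for idx, raw in enumerate(self._source.iter_raw()):
            if idx >= end:
                break
            if idx < start:
                continue
            yield idx, self._process(raw)
            yielded += 1
        if yielded < len(self.frame_range):
            warnings.warn(
                f"{self.meta.path or 'stream'}: expected "
                f"{len(self.frame_range)} frames, decoded {yielded}; "
                "trailing frames were unreadable",
                RuntimeWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.meta.frame_count

    def restrict(self, frame_range: FrameRange) -> "FrameStream":
        """New stream over the same source with a narrower frame range."""
        return FrameStream(
            self._source, self.crop, frame_range, self.downsample_factor
        )

    def frames(self) -> Iterator[np.ndarray]:
        """Iterate over frames only, without indices."""
        for _, frame in self:
            yield frame


def _make_source(path: Path) -> _Source:
    if not path.exists():
        raise VideoDecodeError(f"video file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _TiffSource(path)
    return _ImageIOSource(path)


def open_video(
    path,
    crop: Optional[CropRegion] = None,
    frame_range: Optional[FrameRange] = None,
    downsample_factor: Optional[float] = None,
) -> FrameStream:
    """Open a video file as a streaming sequence of grayscale frames.

    Parameters
    ----------
    path
        Video file. Multipage TIFF is always supported (lossless); other
        containers depend on the installed imageio plugins.
    crop
        Rectangular region kept from each frame, applied before downsampling.
    frame_range
        Restrict analysis to ``[start, end)`` source frame indices.
    downsample_factor
        Shrink divisor ``f``: output dimensions are ``round(dim / f)``
        (bilinear). ``None`` or 1 keeps native resolution.
    """
    return FrameStream(_make_source(Path(path)), crop, frame_range, downsample_factor)


def probe_video(path) -> VideoMeta:
    """Return native fps, frame count and dimensions of a video file."""
    src = _make_source(Path(path))
    return VideoMeta(
        path=src.path,
        fps=src.fps,
        frame_count=src.frame_count,
        height=src.height,
        width=src.width,
    )


def array_stream(
    stack: np.ndarray,
    fps: float = DEFAULT_FPS,
    crop: Optional[CropRegion] = None,
    frame_range: Optional[FrameRange] = None,
    downsample_factor: Optional[float] = None,
) -> FrameStream:
    """Wrap an in-memory ``(frames, height, width[, channels])`` stack."""
    return FrameStream(_ArraySource(stack, fps), crop, frame_range, downsample_factor)


def write_video(path, stack: np.ndarray, fps: float = DEFAULT_FPS) -> Path:
    """Write a frame stack to a lossless multipage TIFF with fps metadata."""
    import tifffile

    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, height, width) grayscale stack")
    data = np.clip(np.round(stack), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, metadata={"fps": float(fps)})
    return path
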