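"""Time-binned summaries, CSV writers, batch processing, and static plots.

Bins are half-open frame-index intervals ``[start, end)``. The step distance
recorded on frame ``t`` (from ``t-1``) belongs to the bin containing ``t``,
and the first frame's distance is 0, so non-overlapping bins tiling a
session sum exactly to the whole-session distance. A seconds-based helper
converts wall-clock bins to frame bins via the video fps.

Batch processing applies one parameter set to every matching video in a
folder (the reference frame is always regenerated from each video itself);
per-file failures are logged and do not abort the batch.
"""

from __future__ import annotations

import fnmatch
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .freezing import FreezeParams, measure_session
from .location import (
    ROI,
    LocationParams,
    ScaleCalibration,
    TrackingResult,
    make_reference,
    track_session,
)
from .video_io import CropRegion, FrameRange, VideoDecodeError, open_video

logger = logging.getLogger(__name__)

__all__ = [
    "Bin",
    "BinSpec",
    "bins_from_seconds",
    "summarize_location",
    "summarize_freeze",
    "summarize",
    "occupancy_heatmap",
    "BatchConfig",
    "BatchResult",
    "run_batch",
    "make_location_plots",
    "make_freeze_plots",
]


@dataclass(frozen=True)
class Bin:
    label: str
    start: int
    end: int  # half-open

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"bin {self.label!r}: start must be < end")


BinSpec = Sequence[Bin]


def _check_bins(bins: BinSpec) -> None:
    labels = [b.label for b in bins]
    if len(set(labels)) != len(labels):
        raise ValueError("bin labels must be unique")


def bins_from_seconds(
    spec: Sequence[tuple[str, float, float]], fps: float
) -> list[Bin]:
    """Convert ``(label, start_s, end_s)`` bins to frame bins via fps
    (half-open, rounded to nearest frame)."""
    return [
        Bin(label, int(round(s * fps)), int(round(e * fps))) for label, s, e in spec
    ]


def session_bin(df: pd.DataFrame, label: str = "session") -> Bin:
    lo, hi = int(df["frame"].min()), int(df["frame"].max()) + 1
    return Bin(label, lo, hi)


def summarize_location(result: TrackingResult, bins: BinSpec) -> pd.DataFrame:
    """Per-bin distance totals and ROI occupancy proportions.

    A bin extending past the analyzed range raises; a trailing bin is
    allowed to be partial only through its recorded ``n_frames``.
    """
    _check_bins(bins)
    df = result.data
    lo, hi = int(df["frame"].min()), int(df["frame"].max()) + 1
    rows = []
    scaled_col = (
        f"distance_{result.calibration.unit_label}" if result.calibration else None
    )
    for b in bins:
        if b.start < lo or b.start >= hi:
            raise ValueError(
                f"bin {b.label!r} [{b.start}, {b.end}) outside analyzed "
                f"frames [{lo}, {hi})"
            )
        sel = df[(df["frame"] >= b.start) & (df["frame"] < b.end)]
        row = {
            "file": result.file or "",
            "bin": b.label,
            "start": b.start,
            "end": b.end,
            "n_frames": len(sel),
            "partial": int(len(sel) < b.end - b.start),
            "distance_px": float(sel["distance_px"].sum()),
        }
        if scaled_col:
            row[scaled_col] = float(sel[scaled_col].sum())
        for name in result.roi_names:
            row[f"roi_{name}"] = float(sel[name].mean()) if len(sel) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_freeze(framewise: pd.DataFrame, bins: BinSpec) -> pd.DataFrame:
    """Per-bin mean motion and percent freezing from a freeze-pipeline
    frame-by-frame table (freezing encoded 0/100, so the mean is the
    percentage directly)."""
    _check_bins(bins)
    lo, hi = int(framewise["frame"].min()), int(framewise["frame"].max()) + 1
    rows = []
    for b in bins:
        if b.start < lo or b.start >= hi:
            raise ValueError(
                f"bin {b.label!r} [{b.start}, {b.end}) outside analyzed "
                f"frames [{lo}, {hi})"
            )
        sel = framewise[(framewise["frame"] >= b.start) & (framewise["frame"] < b.end)]
        rows.append(
            {
                "file": sel["file"].iloc[0] if len(sel) else "",
                "bin": b.label,
                "start": b.start,
                "end": b.end,
                "n_frames": len(sel),
                "partial": int(len(sel) < b.end - b.start),
                "mean_motion": float(sel["motion"].mean()),
                "percent_freezing": float(sel["freezing"].mean()),
            }
        )
    return pd.DataFrame(rows)


def summarize(result, bins: BinSpec) -> pd.DataFrame:
    """Dispatch to the location or freeze summarizer by result type."""
    if isinstance(result, TrackingResult):
        return summarize_location(result, bins)
    if isinstance(result, pd.DataFrame) and "motion" in result.columns:
        return summarize_freeze(result, bins)
    raise TypeError(f"cannot summarize object of type {type(result).__name__}")


def occupancy_heatmap(
    result: TrackingResult, shape: Optional[tuple[int, int]] = None
) -> np.ndarray:
    """2D occupancy count matrix from per-frame positions; total count
    equals the number of analyzed frames."""
    if shape is None:
        shape = result.reference.shape
    h, w = shape
    counts = np.zeros((h, w))
    ys = np.clip(np.round(result.data["y"]).astype(int), 0, h - 1)
    xs = np.clip(np.round(result.data["x"]).astype(int), 0, w - 1)
    np.add.at(counts, (ys, xs), 1)
    return counts


# ---------------------------------------------------------------------------
# Batch processing


@dataclass
class BatchConfig:
    """Shared settings applied to every video matched in ``input_dir``."""

    input_dir: Path
    output_dir: Path
    pattern: str = "*.tif"
    crop: Optional[CropRegion] = None
    frame_range: Optional[FrameRange] = None
    downsample_factor: Optional[float] = None
    location_params: Optional[LocationParams] = None
    freeze_params: Optional[FreezeParams] = None
    rois: Sequence[ROI] = ()
    calibration: Optional[ScaleCalibration] = None
    bins: Optional[BinSpec] = None


@dataclass
class BatchResult:
    framewise_csvs: list[Path] = field(default_factory=list)
    summary_csv: Optional[Path] = None
    log_file: Optional[Path] = None
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _process_one(path: Path, config: BatchConfig, pipeline: str) -> tuple:
    stream = open_video(
        path,
        crop=config.crop,
        frame_range=config.frame_range,
        downsample_factor=config.downsample_factor,
    )
    if pipeline == "location":
        params = config.location_params or LocationParams()
        # batch contract: the reference always comes from the video itself
        reference = make_reference(stream, params)
        result = track_session(
            stream, reference, params, rois=config.rois, cal=config.calibration
        )
        framewise = result.data.copy()
        framewise.insert(0, "file", result.file or str(path))
        bins = list(config.bins) if config.bins else [session_bin(result.data)]
        summary = summarize_location(result, bins)
    else:
        if config.freeze_params is None:
            raise ValueError("freeze pipeline requires freeze_params")
        framewise = measure_session(stream, config.freeze_params)
        bins = list(config.bins) if config.bins else [session_bin(framewise)]
        summary = summarize_freeze(framewise, bins)
    return framewise, summary


def run_batch(config: BatchConfig, pipeline: str = "location") -> BatchResult:
    """Process every matching video in a folder with identical parameters.

    Writes ``<stem>_framewise.csv`` per video, a combined ``summary.csv``,
    and ``batch_log.txt``. A failure on one file is recorded and the batch
    continues; an empty match set raises.
    """
    if pipeline not in ("location", "freeze"):
        raise ValueError("pipeline must be 'location' or 'freeze'")
    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        raise ValueError(f"input folder does not exist: {in_dir}")
    files = sorted(p for p in in_dir.iterdir() if fnmatch.fnmatch(p.name, config.pattern))
    if not files:
        raise ValueError(f"no files matching {config.pattern!r} in {in_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    result = BatchResult()
    summaries = []
    log_lines = []
    for path in files:
        try:
            framewise, summary = _process_one(path, config, pipeline)
        except Exception as exc:
            result.failures[path.name] = str(exc)
            log_lines.append(f"FAIL {path.name}: {exc}")
            logger.error("batch: %s failed: %s", path.name, exc)
            logger.debug("%s", traceback.format_exc())
            continue
        csv_path = out_dir / f"{path.stem}_framewise.csv"
        framewise.to_csv(csv_path, index=False)
        result.framewise_csvs.append(csv_path)
        summaries.append(summary)
        log_lines.append(f"OK   {path.name}: {len(framewise)} frames")

    if summaries:
        summary_csv = out_dir / "summary.csv"
        pd.concat(summaries, ignore_index=True).to_csv(summary_csv, index=False)
        result.summary_csv = summary_csv
    log_file = out_dir / "batch_log.txt"
    log_file.write_text("\n".join(log_lines) + "\n")
    result.log_file = log_file
    return result


# ---------------------------------------------------------------------------
# Static plots


def make_location_plots(result: TrackingResult, out_dir) -> list[Path]:
    """Trajectory over the reference frame, occupancy heatmap, and the
    distance-per-frame trace, as static PNG files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(result.reference.image, cmap="gray", vmin=0, vmax=255)
    ax.plot(result.data["x"], result.data["y"], ".-", ms=2, lw=0.5, color="crimson")
    ax.set_title("trajectory over reference frame")
    p = out / "trajectory.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    counts = occupancy_heatmap(result)
    ax.imshow(counts, cmap="hot")
    ax.set_title("occupancy heatmap")
    p = out / "heatmap.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(result.data["frame"], result.data["distance_px"], lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("distance (px)")
    ax.set_title("per-frame distance")
    p = out / "distance.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    return paths


def make_freeze_plots(framewise: pd.DataFrame, out_dir) -> list[Path]:
    """Motion trace with freezing epochs shaded, as a static PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 3))
    frames = framewise["frame"].to_numpy()
    ax.plot(frames, framewise["motion"], color="steelblue", lw=0.8, label="motion")
    freezing = framewise["freezing"].to_numpy() > 0
    ax.fill_between(
        frames,
        0,
        framewise["motion"].max() or 1,
        where=freezing,
        color="gray",
        alpha=0.4,
        label="freezing",
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("changed pixels")
    ax.legend(loc="upper right")
    p = out / "motion_freezing.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    return [p]


def plot_calibration_histogram(report, out_path) -> Path:
    """Histogram of the empty-arena null distribution with the suggested
    motion threshold marked."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    centers = 0.5 * (report.histogram_edges[:-1] + report.histogram_edges[1:])
    ax.bar(centers, report.histogram_counts, width=np.diff(report.histogram_edges))
    ax.axvline(report.suggested_mt, color="crimson", ls="--", label="suggested MT")
    ax.set_xlabel("filtered |pixel change|")
    ax.set_ylabel("count")
    ax.set_yscale("log")
    ax.legend()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
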