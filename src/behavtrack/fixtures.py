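"""Synthetic behavior videos with known ground truth.

Every scene is a dark (or light) anti-aliased disk — the animal — moving
over a uniform or linearly graded background, with optional bounded integer
sensor noise, an optional interfering blob entering the field of view, and
optional scripted stationary (freezing) epochs. The renderer returns the
true trajectory and freeze script alongside the pixel data, so tracking
error, distance error, ROI occupancy, and freezing recovery can all be
scored against construction-time truth without any recorded video.

Disks are rendered with 4x supersampled anti-aliasing, making the sub-pixel
centroid of the rendered mask meaningful (it matches the nominal center to
better than 0.1 px). Noise is i.i.d. uniform *integer* noise in
``[-amp, amp]``: bounded noise lets thresholds be placed analytically above
the noise floor. Rendering the same spec with the same seed twice yields
identical pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .video_io import FrameStream, array_stream, write_video

__all__ = [
    "Trajectory",
    "DistractorSpec",
    "SceneSpec",
    "FixtureBundle",
    "render_scene",
    "make_freeze_fixture",
    "line_trajectory",
    "stationary_trajectory",
    "billiard_trajectory",
    "write_bundle",
    "PRESETS",
    "make_preset",
]

SUPERSAMPLE = 4


@dataclass(frozen=True)
class Trajectory:
    """True per-frame centroid positions, one ``(x, y)`` per frame."""

    positions: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def path_length(self) -> float:
        """Sum of Euclidean steps between successive positions."""
        p = np.asarray(self.positions)
        return float(np.hypot(*(np.diff(p, axis=0).T)).sum()) if len(p) > 1 else 0.0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)


@dataclass(frozen=True)
class DistractorSpec:
    """A second blob composited on selected frames (an experimenter's hand,
    a cable tip...)."""

    x: float
    y: float
    radius: float
    intensity: float
    frames: tuple[int, ...]  # frame indices on which the blob is present
    #: uniform positional jitter (+/- px) per appearance; a nonzero jitter
    #: keeps per-pixel occlusion below 50% so the median reference stays
    #: clean, as with a hand that never lands in exactly the same spot
    jitter: float = 0.0


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; rendering is a pure function
    of (spec, seed)."""

    height: int = 120
    width: int = 160
    n_frames: int = 100
    fps: float = 30.0
    background: float = 200.0
    background_gradient: Optional[tuple[float, float]] = None  # left, right levels
    disk_radius: float = 6.0
    disk_intensity: float = 30.0
    trajectory: Optional[Trajectory] = None
    noise_amp: int = 0
    seed: int = 0
    distractor: Optional[DistractorSpec] = None
    freeze_script: tuple[tuple[int, int], ...] = ()

    def validate(self) -> None:
        if self.trajectory is None:
            raise ValueError("SceneSpec requires a trajectory")
        if len(self.trajectory) != self.n_frames:
            raise ValueError(
                f"trajectory has {len(self.trajectory)} entries for "
                f"{self.n_frames} frames"
            )
        r = self.disk_radius
        for i, (x, y) in enumerate(self.trajectory.positions):
            if not (r <= x <= self.width - 1 - r and r <= y <= self.height - 1 - r):
                raise ValueError(
                    f"trajectory point {i} ({x:.1f}, {y:.1f}) leaves the frame "
                    f"(disk radius {r})"
                )
        prev_end = 0
        for s, e in sorted(self.freeze_script):
            if s < prev_end:
                raise ValueError("freeze intervals must not overlap")
            if not (0 <= s < e <= self.n_frames):
                raise ValueError(f"freeze interval [{s}, {e}) out of range")
            prev_end = e


@dataclass
class FixtureBundle:
    """Rendered pixels plus ground truth."""

    stack: np.ndarray  # (n_frames, height, width) float, clipped to [0, 255]
    trajectory: Trajectory
    spec: SceneSpec
    freeze_script: tuple[tuple[int, int], ...] = ()

    def stream(self, **kwargs) -> FrameStream:
        """In-memory FrameStream over the rendered stack."""
        return array_stream(self.stack, fps=self.spec.fps, **kwargs)

    def write(self, path) -> Path:
        return write_video(path, self.stack, fps=self.spec.fps)

    @property
    def true_path_length(self) -> float:
        return self.trajectory.path_length


def disk_alpha(
    height: int, width: int, cx: float, cy: float, radius: float
) -> np.ndarray:
    """Anti-aliased disk coverage mask (values in [0, 1]), 4x supersampled."""
    alpha = np.zeros((height, width))
    pad = int(math.ceil(radius)) + 1
    x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, width)
    y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, height)
    if x0 >= x1 or y0 >= y1:
        return alpha
    ss = SUPERSAMPLE
    # subpixel sample offsets within each pixel, centered on pixel centers
    off = (np.arange(ss) + 0.5) / ss - 0.5
    xs = np.arange(x0, x1)[:, None] + off[None, :]  # (nx, ss)
    ys = np.arange(y0, y1)[:, None] + off[None, :]
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    inside = (dy2[:, None, :, None] + dx2[None, :, None, :]) <= radius**2
    alpha[y0:y1, x0:x1] = inside.mean(axis=(2, 3))
    return alpha


def _background(spec: SceneSpec) -> np.ndarray:
    if spec.background_gradient is not None:
        lo, hi = spec.background_gradient
        row = np.linspace(lo, hi, spec.width)
        return np.tile(row, (spec.height, 1))
    return np.full((spec.height, spec.width), float(spec.background))


def render_scene(spec: SceneSpec) -> FixtureBundle:
    """Render a scene spec to a pixel stack plus ground truth.

    Per frame: composite the disk (and the distractor, on its scheduled
    frames) over the background by alpha blending, add integer noise drawn
    from ``[-noise_amp, noise_amp]``, clip to [0, 255].
    """
    spec.validate()
    assert spec.trajectory is not None
    bg = _background(spec)
    rng = np.random.default_rng(spec.seed)
    jitter_rng = np.random.default_rng(spec.seed + 2)
    distractor_frames = set(spec.distractor.frames) if spec.distractor else set()
    stack = np.empty((spec.n_frames, spec.height, spec.width))
    for t, (x, y) in enumerate(spec.trajectory.positions):
        img = bg.copy()
        a = disk_alpha(spec.height, spec.width, x, y, spec.disk_radius)
        img = img * (1 - a) + spec.disk_intensity * a
        if spec.distractor and t in distractor_frames:
            d = spec.distractor
            dx = dy = 0.0
            if d.jitter:
                dx, dy = jitter_rng.uniform(-d.jitter, d.jitter, size=2)
            ad = disk_alpha(spec.height, spec.width, d.x + dx, d.y + dy, d.radius)
            img = img * (1 - ad) + d.intensity * ad
        if spec.noise_amp:
            img = img + rng.integers(
                -spec.noise_amp, spec.noise_amp, endpoint=True, size=img.shape
            )
        stack[t] = np.clip(img, 0, 255)
    return FixtureBundle(
        stack=stack,
        trajectory=spec.trajectory,
        spec=spec,
        freeze_script=tuple(sorted(spec.freeze_script)),
    )


def empty_arena(
    height: int = 120,
    width: int = 160,
    n_frames: int = 50,
    background: float = 200.0,
    noise_amp: int = 3,
    seed: int = 0,
    fps: float = 30.0,
) -> FixtureBundle:
    """Arena-only video (no animal) for motion-threshold calibration:
    the background plus the same bounded integer sensor noise."""
    spec = SceneSpec(
        height=height, width=width, n_frames=n_frames, fps=fps,
        background=background, noise_amp=noise_amp, seed=seed,
        disk_radius=0.0,
        trajectory=stationary_trajectory(n_frames, width / 2.0, height / 2.0),
    )
    bg = _background(spec)
    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, height, width))
    for t in range(n_frames):
        img = bg.copy()
        if noise_amp:
            img = img + rng.integers(-noise_amp, noise_amp, endpoint=True, size=img.shape)
        stack[t] = np.clip(img, 0, 255)
    return FixtureBundle(stack=stack, trajectory=spec.trajectory, spec=spec)


def line_trajectory(
    n_frames: int,
    x_start: float,
    x_end: float,
    y: float,
    step: float,
) -> Trajectory:
    """Constant-speed zigzag along a row: advance ``step`` px/frame toward
    ``x_end``, reverse at the endpoints. Every per-frame displacement is
    exactly ``step`` when ``(x_end - x_start)`` is a multiple of ``step``."""
    if step <= 0:
        raise ValueError("step must be > 0")
    span = x_end - x_start
    if span <= 0:
        raise ValueError("x_end must exceed x_start")
    pos = []
    x, direction = x_start, 1
    for _ in range(n_frames):
        pos.append((x, y))
        x += direction * step
        if x > x_end or x < x_start:
            direction *= -1
            x += 2 * direction * step
    return Trajectory(tuple(pos))


def stationary_trajectory(n_frames: int, x: float, y: float) -> Trajectory:
    return Trajectory(tuple((x, y) for _ in range(n_frames)))


def billiard_trajectory(
    n_frames: int,
    bounds: tuple[float, float, float, float],
    speed: float,
    angle_deg: float = 30.0,
    start: Optional[tuple[float, float]] = None,
) -> Trajectory:
    """Constant-speed path reflecting off the walls of a rectangle.

    ``bounds`` is ``(x_min, y_min, x_max, y_max)``. Every per-frame
    displacement has length exactly ``speed``, so the true path length is
    ``speed * (n_frames - 1)``. Unlike a one-row shuttle, the path spreads
    pixel occlusion over a 2-D region, which keeps the median reference
    unbiased — the regime an arena-roaming animal actually produces.
    """
    x_min, y_min, x_max, y_max = bounds
    if not (x_min < x_max and y_min < y_max):
        raise ValueError("empty billiard bounds")
    if speed <= 0:
        raise ValueError("speed must be > 0")
    theta = math.radians(angle_deg)
    vx, vy = speed * math.cos(theta), speed * math.sin(theta)
    x, y = start if start is not None else (x_min, y_min)
    pos = [(x, y)]
    for _ in range(n_frames - 1):
        nx, ny = x + vx, y + vy
        for _ in range(4):
            moved = False
            if nx < x_min or nx > x_max:
                vx = -vx
                nx = x + vx
                moved = True
            if ny < y_min or ny > y_max:
                vy = -vy
                ny = y + vy
                moved = True
            if not moved:
                break
        x, y = nx, ny
        pos.append((x, y))
    return Trajectory(tuple(pos))


def make_freeze_fixture(spec: SceneSpec) -> FixtureBundle:
    """Render a session with scripted freezing epochs.

    Outside the freeze intervals the disk performs a jittered random walk
    with per-frame displacement of at least 3 px (reflected at a margin
    from the frame edges). Inside an interval ``[s, e)`` the disk occupies
    the position it reached on frame ``s - 1``, so the frame-to-frame change
    is zero (bar sensor noise) exactly on frames ``s .. e - 1``. Any
    trajectory on the spec is ignored and replaced by the generated walk.
    """
    script = tuple(sorted(spec.freeze_script))
    if not script:
        raise ValueError("make_freeze_fixture requires a non-empty freeze_script")
    rng = np.random.default_rng(spec.seed + 1)  # walk RNG, distinct from noise RNG
    margin = spec.disk_radius + 2
    frozen = np.zeros(spec.n_frames, dtype=bool)
    for s, e in script:
        frozen[s:e] = True

    x = spec.width / 2.0
    y = spec.height / 2.0
    positions = []
    heading = rng.uniform(0, 2 * math.pi)
    for t in range(spec.n_frames):
        if t > 0 and not frozen[t]:
            step = rng.uniform(3.0, 5.0)
            heading += rng.normal(0, 0.6)
            nx = x + step * math.cos(heading)
            ny = y + step * math.sin(heading)
            # reflect off walls, keeping the step length
            for _ in range(8):
                ok = True
                if nx < margin or nx > spec.width - 1 - margin:
                    heading = math.pi - heading
                    ok = False
                if ny < margin or ny > spec.height - 1 - margin:
                    heading = -heading
                    ok = False
                if ok:
                    break
                nx = x + step * math.cos(heading)
                ny = y + step * math.sin(heading)
            nx = min(max(nx, margin), spec.width - 1 - margin)
            ny = min(max(ny, margin), spec.height - 1 - margin)
            x, y = nx, ny
        positions.append((x, y))

    walk_spec = replace(
        spec, trajectory=Trajectory(tuple(positions)), freeze_script=script
    )
    return render_scene(walk_spec)


# ---------------------------------------------------------------------------
# Named presets used by the CLI and the test/acceptance fixtures.

def _preset_track_line(seed: int, noise_amp: int = 0) -> FixtureBundle:
    traj = billiard_trajectory(
        300, bounds=(20, 30, 380, 170), speed=2, angle_deg=27, start=(30, 40)
    )
    return render_scene(
        SceneSpec(
            height=200, width=400, n_frames=300, disk_radius=6,
            disk_intensity=30, background=200, noise_amp=noise_amp, seed=seed,
            trajectory=traj,
        )
    )


def _preset_track_roi(seed: int) -> FixtureBundle:
    # two full shuttle cycles; with an ROI boundary at x = 65 the disk sits
    # inside on exactly 90 of 240 frames (37.5%) by construction
    traj = line_trajectory(240, x_start=20, x_end=140, y=60, step=2)
    return render_scene(
        SceneSpec(
            height=120, width=160, n_frames=240, disk_radius=6,
            disk_intensity=30, background=200, noise_amp=0, seed=seed,
            trajectory=traj,
        )
    )


def _preset_interference(seed: int) -> FixtureBundle:
    # animal roams a small patch ~150 px from the distractor; it must move,
    # or it would contaminate the median reference
    n = 60
    traj = billiard_trajectory(
        n, bounds=(18, 25, 40, 47), speed=2, angle_deg=33, start=(20, 28)
    )
    distractor = DistractorSpec(
        x=160.0, y=95.0, radius=6.0, intensity=30.0,
        frames=tuple(range(n // 2, n)), jitter=10.0,
    )
    return render_scene(
        SceneSpec(
            height=120, width=200, n_frames=n, disk_radius=6,
            disk_intensity=30, background=200, noise_amp=2, seed=seed,
            trajectory=traj, distractor=distractor,
        )
    )


def _preset_freeze(seed: int) -> FixtureBundle:
    return make_freeze_fixture(
        SceneSpec(
            height=120, width=160, n_frames=300, fps=30, disk_radius=6,
            disk_intensity=30, background=200, noise_amp=3, seed=seed,
            freeze_script=((40, 90), (140, 190), (240, 263)),
        )
    )


PRESETS = {
    "track-line": _preset_track_line,
    "track-roi": _preset_track_roi,
    "interference": _preset_interference,
    "freeze": _preset_freeze,
}


def make_preset(name: str, seed: int = 0) -> FixtureBundle:
    """Render one of the named fixture presets."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    return factory(seed)


def write_bundle(bundle: FixtureBundle, out_dir, stem: str) -> dict:
    """Write a bundle as TIFF video + JSON ground-truth sidecar; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    video = bundle.write(out / f"{stem}.tif")
    truth = {
        "trajectory": [list(p) for p in bundle.trajectory.positions],
        "true_path_length": bundle.true_path_length,
        "freeze_script": [list(iv) for iv in bundle.freeze_script],
        "fps": bundle.spec.fps,
        "seed": bundle.spec.seed,
    }
    sidecar = out / f"{stem}_truth.json"
    sidecar.write_text(json.dumps(truth, indent=1))
    return {"video": video, "truth": sidecar}
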