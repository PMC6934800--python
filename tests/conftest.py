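import numpy as np
import pytest

from behavtrack import fixtures as fx
from behavtrack.video_io import array_stream, write_video


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """10-frame 64x64 uint8 stack with moderate structure."""
    return rng.integers(0, 256, size=(10, 64, 64)).astype(np.uint8)


@pytest.fixture
def tiff_video(tmp_path, small_stack):
    path = tmp_path / "clip.tif"
    write_video(path, small_stack, fps=30)
    return path


@pytest.fixture
def tracking_bundle():
    """Noise-free moving-disk scene with exact ground truth."""
    traj = fx.billiard_trajectory(60, (15, 15, 105, 85), speed=2, angle_deg=27,
                                  start=(20, 20))
    return fx.render_scene(
        fx.SceneSpec(height=100, width=120, n_frames=60, disk_radius=6,
                     disk_intensity=30, background=200, noise_amp=0, seed=0,
                     trajectory=traj)
    )


@pytest.fixture
def tracking_stream(tracking_bundle):
    return tracking_bundle.stream()
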