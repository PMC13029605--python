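import numpy as np
import pytest

from acoustopiv.io import FrameSequence
from acoustopiv.synthdata import CameraModel, Trajectories, default_camera, render_frames


@pytest.fixture
def camera() -> CameraModel:
    return default_camera()


@pytest.fixture
def quiet_camera() -> CameraModel:
    """Noise-free camera for deterministic image checks."""
    return CameraModel(noise_sigma=0.0)


def make_particle_frames(
    positions: np.ndarray,
    shifts: np.ndarray,
    shape=(140, 180),
    camera: CameraModel | None = None,
    seed: int = 0,
) -> FrameSequence:
    """Render a two-frame stack where every particle moves by its row of
    ``shifts`` (dx, dy in px) between the frames, wrapping at the edges."""
    camera = camera or CameraModel(noise_sigma=0.0)
    pitch = camera.pixel_pitch_um
    h, w = shape
    p0 = np.asarray(positions, dtype=float)
    p1 = np.mod(p0 + np.atleast_2d(shifts), [w, h])
    pos_um = np.stack([p0, p1]) * pitch
    vel = np.zeros_like(pos_um)
    traj = Trajectories(
        positions_um=pos_um,
        velocities_mm_s=vel,
        times=np.arange(2) / camera.frame_rate,
        roi_size_um=(w * pitch, h * pitch),
        camera=camera,
    )
    return render_frames(traj, camera, seed=seed)


def random_positions(rng: np.random.Generator, n: int, shape=(140, 180), margin: float = 0.0):
    h, w = shape
    return np.column_stack(
        [rng.uniform(margin, w - margin, n), rng.uniform(margin, h - margin, n)]
    )


@pytest.fixture
def frame_pair_factory():
    return make_particle_frames
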