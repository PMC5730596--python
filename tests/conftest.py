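import numpy as np
import pytest

from larvatrack.io import FrameSequence
from larvatrack.synthetic import BurstMotion, LarvaModel, SceneConfig, SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A small clean single-larva scene rendered once per session."""
    spec = SceneSpec(
        "clean_small",
        "clean round well, one larva",
        SceneConfig(image_size=96, well_radius=40.0, n_frames=220, seed=404),
        n_larvae=1,
    )
    return generate_scene(spec)


@pytest.fixture
def constant_sequence():
    frames = np.full((30, 16, 16), 128, dtype=np.uint8)
    return FrameSequence(frames, frame_rate=15.0)
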