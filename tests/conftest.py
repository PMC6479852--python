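import numpy as np
import pytest

from stumprot.simdata import SceneParams, generate_scenes


@pytest.fixture(scope="session")
def small_scene_params():
    """Small frames keep the invariant sweeps cheap."""
    return SceneParams(image_height=96, image_width=128,
                       stump_radius_range=(0.12, 0.4))


@pytest.fixture(scope="session")
def scene_batch(small_scene_params):
    """A reusable batch of 120 small scenes spanning all three grades."""
    return generate_scenes((60, 24, 36), small_scene_params, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
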