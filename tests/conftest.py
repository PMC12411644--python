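import numpy as np
import pytest

from polcontrast.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene_config():
    """A quick 96x96 scene for smoke-level tests."""
    return SceneConfig(
        seed=42,
        shape=(96, 96),
        ellipse_center=(44.0, 48.0),
        ellipse_axes=(22.0, 15.0),
        ellipse_rotation=0.2,
        fiducials=((8.0, 8.0), (8.0, 88.0), (88.0, 8.0), (88.0, 88.0)),
    )
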