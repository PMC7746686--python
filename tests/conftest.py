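import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octarep.synth import SceneSpec
from octarep.types import EnFaceAngiogram

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> SceneSpec:
    """Full-size 800 x 534 widefield grid at the standard pitch."""
    return SceneSpec(seed=7)


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """Quarter-ish grid for fast scene tests (same pitch, smaller field)."""
    return SceneSpec(width_px=256, height_px=170, seed=7)


@pytest.fixture()
def flat_image() -> EnFaceAngiogram:
    return EnFaceAngiogram(np.full((128, 128), 0.5), 15.0, 15.0)


@pytest.fixture()
def bar_image() -> EnFaceAngiogram:
    """Horizontal bright bar (2 px = 30 um wide) on dark background."""
    px = np.full((120, 200), 0.1)
    px[59:61, :] = 0.9
    return EnFaceAngiogram(px, 15.0, 15.0)
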