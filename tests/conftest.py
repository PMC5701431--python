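import numpy as np
import pytest

from lipilyzer.lut import ColorLUT, build_lut
from lipilyzer.synthetic import SceneSpec, constant_field


@pytest.fixture(scope="session")
def lut() -> ColorLUT:
    """Default thickness->RGB table (0-240 nm, 6500 K, CIE 1964)."""
    return build_lut()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def small_scene(**overrides) -> SceneSpec:
    """A quarter-scale stationary scene for fast geometry unit tests."""
    defaults = dict(
        shape=(200, 260),
        eye_path=((100, 130),),
        pupil_radius=20.0,
        iris_radius=60.0,
        thickness_field=constant_field(70.0),
        noise_sigma=0.0,
        iris_texture_sigma=0.0,
        seed=7,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)
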