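import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rok

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_aperture():
    return rok.ApertureSpec(width=600, height=600)


def make_scene(
    n=20,
    coherence=0.65,
    opposite=0.35,
    speed=3.0,
    size=1.0,
    direction=90.0,
    shape=rok.ApertureShape.rectangular,
    fade_out=False,
    **layer_kwargs,
):
    """Small single-layer two-direction scene used across the suite."""
    aperture = rok.ApertureSpec(width=600, height=600, shape=shape, fade_out=fade_out)
    kwargs = dict(
        number_of_oobs=n,
        coherence_movement=coherence,
        coherence_movement_opposite=opposite,
        coherence_orientation=coherence,
        coherence_orientation_opposite=opposite,
        coherent_movement_direction=direction,
        coherent_orientation=direction,
        movement_speed=speed,
        oob_size=size,
        oob_color=(128, 0, 128),
    )
    kwargs.update(layer_kwargs)
    return rok.SceneSpec(apertures=[(aperture, rok.LayerSpec(**kwargs))])


@pytest.fixture
def small_scene():
    return make_scene(n=5)
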