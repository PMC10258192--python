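import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crowdscope.synthetic_scenes import (
    NoiseModel, SensorModel, make_scene, render_fret_images,
)

settings.register_profile(
    "crowdscope",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("crowdscope")


@pytest.fixture
def default_sensor():
    return SensorModel()


@pytest.fixture
def clean_scene_factory():
    """Scene + noiseless render with exact two-level concentration/crowding."""

    def factory(mode="aggregation", crowding_dense=0.4, crowding_dilute=0.3,
                sensor=None, seed=0, **kwargs):
        sensor = sensor or SensorModel()
        kwargs.setdefault("width", 96)
        kwargs.setdefault("height", 96)
        kwargs.setdefault("n_condensates", 4)
        scene = make_scene(crowding_dense=crowding_dense,
                           crowding_dilute=crowding_dilute,
                           mode_label=mode, seed=seed, **kwargs)
        channels = render_fret_images(scene, sensor, noise=None)
        return scene, channels, sensor

    return factory


@pytest.fixture
def default_noise():
    return NoiseModel()
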