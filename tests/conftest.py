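import numpy as np
import pytest

from fidgrid import CameraModel, GridSpec, generate_grid


@pytest.fixture(scope="session")
def binary_spec():
    return GridSpec(scheme="binary", feature_size=10.0, spacing=500.0)


@pytest.fixture(scope="session")
def ternary_spec():
    return GridSpec(scheme="ternary", feature_size=10.0, spacing=500.0)


@pytest.fixture(scope="session")
def small_layout(binary_spec):
    """A 6x6-site grid, enough for multi-code scenes."""
    return generate_grid(binary_spec, (3000.0, 3000.0))


@pytest.fixture()
def centered_camera():
    def make(**kwargs):
        defaults = dict(pixel_size=1.2, image_size=(1300, 1300),
                        rotation=0.0, translation=(1250.0, 1250.0),
                        polarity="bright_features", blur_sigma=0.0,
                        noise_sigma=0.0, seed=0)
        defaults.update(kwargs)
        return CameraModel(**defaults)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
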