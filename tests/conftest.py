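import numpy as np
import pytest

from comsli import (
    PhantomSpec,
    ProfileParams,
    Region,
    generate_phantom,
    single_fiber_spec,
)


@pytest.fixture
def params():
    return ProfileParams()


@pytest.fixture
def single_fiber_stack():
    """Noise-free uniform single-fiber scene, theta = 30 deg, 24 azimuths."""
    spec = single_fiber_spec(shape=(16, 16), theta=30.0)
    return generate_phantom(spec)


@pytest.fixture
def crossing_stack():
    """Noise-free scene with fibers at 0 and 90 deg in every pixel."""
    mask = np.ones((12, 12), dtype=bool)
    spec = PhantomSpec(
        shape=(12, 12), regions=[Region(mask, [(0.0, 1.0), (90.0, 1.0)])]
    )
    return generate_phantom(spec)


def circular_diff(a, b):
    """Half-circle distance used to compare orientations in tests."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 180.0
    return np.minimum(d, 180.0 - d)
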