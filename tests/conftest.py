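import numpy as np
import pytest

from confmap import (
    DensityMap,
    SphereSpec,
    estimate_noise,
    make_volume_phantom,
    place_default_windows,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def noise_map(rng):
    """A 48^3 pure-noise map, variance 0.01, voxel 1.1 A."""
    values = rng.normal(0.0, 0.1, (48, 48, 48))
    return DensityMap(values, (1.1, 1.1, 1.1))


@pytest.fixture
def planted_phantom():
    """A 64^3 phantom with a soft central sphere 8 noise-sd high."""
    return make_volume_phantom(
        64, [SphereSpec((0.0, 0.0, 0.0), 5.0, 0.8, 2.5)], 0.01, seed=11
    )


@pytest.fixture
def planted_noise(planted_phantom):
    dm = planted_phantom.as_density_map()
    return dm, estimate_noise(place_default_windows(dm))
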