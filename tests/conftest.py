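import numpy as np
import pytest

import hermesim as hs


@pytest.fixture(scope="session")
def gauss_noise():
    return hs.normal_noise(1.0)


@pytest.fixture(scope="session")
def additive_kernel(gauss_noise):
    return hs.make_additive(gauss_noise)


@pytest.fixture(scope="session")
def tjonwu_kernel():
    return hs.make_multiplicative(hs.uniform01_noise())


@pytest.fixture(scope="session")
def interpolation_kernel():
    return hs.make_interpolation(hs.uniform_sym_noise(1.0))


@pytest.fixture(scope="session")
def midpoint_kernel():
    return hs.make_midpoint()


@pytest.fixture(scope="session")
def normal_02_grid():
    """Normal(0, variance 2) probability density on a fine grid."""
    return hs.GridDensity.from_function(
        lambda z: np.exp(-z ** 2 / 4.0) / np.sqrt(4.0 * np.pi),
        -10.0, 10.0, 2048, normalize=True)


def random_atomic_probability(rng, n=8, mean=None, span=2.0):
    """Random atomic probability measure, optionally recentred to a mean."""
    locs = rng.uniform(-span, span, n)
    w = rng.uniform(0.2, 1.0, n)
    w = w / w.sum()
    mu = hs.AtomicMeasure(locs, w)
    if mean is not None:
        mu = hs.AtomicMeasure(locs - mu.mean + mean, w)
    return mu
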