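import numpy as np
import pytest

from radperturb import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Uniform-intensity 10 mm sphere on a 1 mm grid (analytic reference)."""
    spec = PhantomSpec(shape=(32, 32, 32), spacing=(1, 1, 1), radii=(10, 10, 10))
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def textured_phantom():
    """Random-texture sphere with noise, for perturbation/feature tests."""
    spec = PhantomSpec(
        shape=(40, 40, 40), spacing=(1, 1, 1), radii=(10, 10, 10),
        texture="random", noise_sd=5.0, seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
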