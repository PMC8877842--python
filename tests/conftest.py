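import numpy as np
import pytest

import sssnet as s


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic circular phantom with analytic geometry."""
    params = s.PhantomParams(image_size=128, outer_radius=50, zp_thickness=6,
                             te_thickness=11, icm_radius=18, ellipticity=1.0,
                             noise_sigma=0.0, illumination_gradient=0.0,
                             seed=0)
    return s.generate_phantom(params)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A handful of noisy 64x64 phantoms for pipeline tests."""
    phantoms, manifest = s.generate_dataset(6, seed=42, image_size=64)
    return phantoms, manifest
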