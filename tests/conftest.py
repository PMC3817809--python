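import numpy as np
import pytest
from hypothesis import settings

import conefit as cf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A fast synthetic spec: 4 sources, small image, short movie."""
    return cf.SyntheticSpec(
        n_sources=4, m=120, height=24, width=24, cluster_radius=5.0,
        sigma_noise=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def small_noise_free_disjoint():
    """Noise-free movie with non-overlapping clusters plus its ground truth."""
    spec = cf.SyntheticSpec(
        n_sources=4, m=120, height=24, width=24, cluster_radius=4.0,
        sigma_noise=0.0, seed=3,
    )
    movie, truth = cf.generate_movie(spec)
    assert truth.overlap_pixels().size == 0
    return movie, truth


@pytest.fixture(scope="session")
def default_movie():
    """One default-condition benchmark movie (16 sources, 60x60, m=400)."""
    return cf.generate_movie(cf.SyntheticSpec(seed=11))
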