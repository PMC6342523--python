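import numpy as np
import pytest

from caldemix.synth import SynthParams, generate_movie


@pytest.fixture(scope="session")
def small_movie():
    """32x32x400 movie with 5 well-separated neurons at 10-sigma peaks."""
    params = SynthParams(fov_dims=(32, 32), n_frames=400, n_neurons=5, seed=11)
    movie, truth = generate_movie(params)
    return movie, truth


@pytest.fixture(scope="session")
def noiseless_movie():
    """Noiseless, background-free movie: exact rank-N ground truth."""
    params = SynthParams(
        fov_dims=(32, 32),
        n_frames=300,
        n_neurons=3,
        noise_sigma=0.0,
        background_rank=0,
        seed=7,
    )
    movie, truth = generate_movie(params)
    return movie, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
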