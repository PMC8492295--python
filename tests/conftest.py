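import numpy as np
import pytest

from cgdenoise.synthetic import NoiseSpec, PairedSample, add_noise, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom():
    return make_phantom(64, 64, complexity=3, seed=7)


@pytest.fixture
def paired(phantom):
    spec = NoiseSpec("gaussian", sigma=0.15, seed=3)
    return PairedSample(clean=phantom, noisy=add_noise(phantom, spec), spec=spec)
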