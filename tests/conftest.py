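import numpy as np
import pytest

from pdmotor import synth


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free walk with default parameters and its ground truth."""
    return synth.generate_walk(synth.WalkParameters(noise_sd=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_walk():
    """Default-noise (3 mm) walk drawn from the healthy profile."""
    return synth.generate_walk(synth.GaitProfile.for_group("healthy"), seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
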