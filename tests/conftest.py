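import pytest

from pgisomer import calibration as cal
from pgisomer import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_samples():
    """Default calibration design measured through the noise-free forward model."""
    return syn.make_training_set(noise=syn.NOISELESS)


@pytest.fixture(scope="session")
def noiseless_model(noiseless_samples):
    return cal.fit_model(noiseless_samples)


@pytest.fixture(scope="session")
def noisy_samples():
    """Default design with the default measurement-noise model (fixed seed)."""
    return syn.make_training_set(noise=syn.NoiseModel(seed=42))


@pytest.fixture(scope="session")
def noisy_model(noisy_samples):
    return cal.fit_model(noisy_samples)
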