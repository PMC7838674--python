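import numpy as np
import pytest

from dms_eeg import SynthParams, bundle_from_trials, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """20 balanced synthetic trials with a strong lateralized contrast."""
    params = SynthParams(erd_depth=0.8, seed=42)
    return bundle_from_trials(generate_dataset(20, params))


@pytest.fixture(scope="session")
def noiseless_params():
    return SynthParams(noise_sigma=0.0, erd_depth=0.8, seed=5)
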