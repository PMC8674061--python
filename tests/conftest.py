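import pytest

from eoghci.pipeline import extract_features_frame
from eoghci.preprocess import PreprocessConfig
from eoghci.synthetic import SynthParams, generate_subject


@pytest.fixture(scope="session")
def noisefree_features():
    """Wide feature frame of a noise-free subject (pure task templates
    plus the deterministic mains term)."""
    params = SynthParams(noise_sd=0.0, seed=11)
    ds = generate_subject("NF", params)
    return extract_features_frame(ds.trials, PreprocessConfig())


@pytest.fixture(scope="session")
def default_noise_features():
    """Wide feature frame of one subject at the default noise level."""
    params = SynthParams(seed=1)
    ds = generate_subject("S1", params)
    return extract_features_frame(ds.trials, PreprocessConfig())
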