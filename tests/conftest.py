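import numpy as np
import pytest

from seizurepipe import pipeline as pl
from seizurepipe import synthetic as syn

DEFAULT_SEIZURES = [(600.0, 60.0), (1500.0, 75.0)]


@pytest.fixture(scope="session")
def default_recording():
    """One default 40-min recording with two seizures and ground truth."""
    params = syn.GeneratorParams(rng_seed=1)
    return syn.generate_recording(syn.ProtocolSpec(), DEFAULT_SEIZURES, params)


@pytest.fixture(scope="session")
def default_params():
    return syn.GeneratorParams(rng_seed=1)


@pytest.fixture(scope="session")
def processed(default_recording):
    """Beat series + unlabeled feature table of the default recording."""
    rec, _ = default_recording
    return pl.process_recording(rec, pl.default_config()["filters"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
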