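import numpy as np
import pytest

from sophase import preprocess
from sophase.synthgen import SignalGenConfig, generate_recording


@pytest.fixture(scope="session")
def short_recording():
    """10-min default-condition synthetic recording, shared across tests."""
    cfg = SignalGenConfig(duration=600.0, seed=3)
    rec, hyp, gt = generate_recording(cfg)
    return cfg, rec, hyp, gt


@pytest.fixture(scope="session")
def short_prepared(short_recording):
    """Standardized recording with analysis mask and the generator truth."""
    cfg, rec, hyp, gt = short_recording
    rec_std = preprocess.standardize(rec)
    amask = preprocess.artifact_mask(rec_std)
    usable = preprocess.analysis_mask(rec_std, hyp, amask)
    return cfg, rec_std, usable, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
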