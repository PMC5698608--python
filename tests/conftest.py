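import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ppgwave as pw

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_record():
    """Noise- and drift-free synthetic record with ground-truth peaks."""
    cfg = pw.SyntheticConfig(duration=30.0, hr_mean=72.0, hr_sd=2.0, drift=(),
                             noise_sd=0.0, seed=7)
    return pw.generate_ppg(cfg)


@pytest.fixture
def drifting_record():
    """Pulse train riding on a 0.2 Hz drift of twice the pulse amplitude."""
    cfg = pw.SyntheticConfig(duration=60.0, hr_mean=72.0, hr_sd=0.0,
                             drift=((0.2, 2.0),), noise_sd=0.0, seed=5)
    return pw.generate_ppg(cfg)
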