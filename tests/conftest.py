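import warnings

import numpy as np
import pytest

from ppgbp.synthetic import SubjectProfile, generate_record

FS = 125.0

# the shan15-1 admissibility warning is expected and exercised explicitly
# in the wavelet tests; silence it everywhere else
warnings.filterwarnings("ignore", message="shan parameters")


@pytest.fixture(scope="session")
def normal_profile():
    return SubjectProfile(sbp_target=110.0, dbp_target=72.0, heart_rate=60.0, seed=42)


@pytest.fixture(scope="session")
def clean_record(normal_profile):
    """20 s noiseless record at normal BP."""
    return generate_record(normal_profile, n_samples=2500, fs=FS)


@pytest.fixture(scope="session")
def stage2_record():
    profile = SubjectProfile(sbp_target=150.0, dbp_target=95.0, heart_rate=70.0, seed=7)
    return generate_record(profile, n_samples=2500, fs=FS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
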