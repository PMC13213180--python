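import numpy as np
import pytest

from hreflex import (
    RecruitmentTruth,
    SweepProtocol,
    WaveformSpec,
    generate_run,
)


@pytest.fixture(scope="session")
def truth():
    return RecruitmentTruth()


@pytest.fixture(scope="session")
def protocol():
    return SweepProtocol()


@pytest.fixture(scope="session")
def clean_wspec():
    """Noise-free, variability-free waveforms: measurements must equal truth."""
    return WaveformSpec(noise_rms=0.0, trial_cv=0.0)


@pytest.fixture(scope="session")
def noisy_wspec():
    return WaveformSpec()


@pytest.fixture(scope="session")
def clean_run(truth, protocol, clean_wspec):
    return generate_run(truth, protocol, clean_wspec, subject_id="CLEAN", seed=11)


@pytest.fixture(scope="session")
def noisy_run(truth, protocol, noisy_wspec):
    return generate_run(truth, protocol, noisy_wspec, subject_id="NOISY", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
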