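import numpy as np
import pytest

from hepaflow import AifSpec, FrameSchedule, SubjectSpec, generate_aif, generate_subject


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def aif():
    """Default gamma-variate arterial input on the 280-s grid."""
    return generate_aif(AifSpec())


@pytest.fixture(scope="session")
def clean_subject():
    """One noise-free synthetic subject at the default ground truth."""
    return generate_subject(SubjectSpec(noise_fraction=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
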