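import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from eegid.data_io import MONTAGES, Recording, Session
from eegid.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """A fast 4-subject cohort: 8 s of 8-channel signal at 160 Hz."""
    return SyntheticSpec(
        n_subjects=4, n_channels=8, n_sources=4, duration_s=8.0, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture
def rec64() -> Recording:
    """A 64-channel recording with deterministic content, 2 s at 160 Hz."""
    rng = np.random.default_rng(42)
    return Recording(
        subject_id="S001",
        session=Session.EO,
        channel_names=list(MONTAGES["FULL64"].channels),
        sample_rate=160.0,
        signal=rng.normal(size=(64, 320)),
    )
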