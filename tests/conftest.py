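import numpy as np
import pytest

from affectstream.devices import builtin_profile
from affectstream.synthgen import SynthConfig, generate_session


@pytest.fixture(scope="session")
def muse():
    return builtin_profile("muse_s")


def tiny_synth_config(seed=0, **overrides):
    """A short 4-video session (~2 min of signal) for fast end-to-end tests."""
    defaults = dict(
        profile=builtin_profile("muse_s"),
        n_videos=4,
        duration_mean=20.0,
        duration_sd=4.0,
        duration_range=(12.0, 30.0),
        gap_range=(4.0, 8.0),
        lead_in=5.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_session():
    return generate_session(tiny_synth_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
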