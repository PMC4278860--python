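"""Shared fixtures: surrogate sessions at the scales the suite needs.

Session-scoped so that the expensive generation + feature extraction run
once; tests must not mutate fixture arrays in place (copy first).
"""

import numpy as np
import pytest

from ecogkin import SynthConfig, extract_features, generate_session


@pytest.fixture(scope="session")
def default_session():
    """The reference study conditions: 16 channels, 40 reaches, ~8 min."""
    return generate_session(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_session):
    return extract_features(default_session)


@pytest.fixture(scope="session")
def small_session():
    """A shorter session with the default encoding, for fast CV tests."""
    return generate_session(SynthConfig(seed=2, n_channels=12, n_reaches=15))


@pytest.fixture(scope="session")
def small_features(small_session):
    return extract_features(small_session)


@pytest.fixture(scope="session")
def noiseless_features():
    """Near-noiseless strong encoding along a pinned reach direction."""
    cfg = SynthConfig(
        seed=7,
        informative=((0, "high_gamma_2", 4.0, 0.0), (3, "high_gamma_2", 4.0, 0.0)),
        pink_rms_uv=0.0,
        n_reaches=24,
        reach_duration_s=(5.0, 6.2),
        rest_duration_s=(1.0, 4.0),
        home_fraction=(0.05, 0.05, 0.05),
    )
    return extract_features(generate_session(cfg))
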