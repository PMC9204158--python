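"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import emgrasp as eg


@pytest.fixture(scope="session")
def small_config() -> eg.SyntheticProtocolConfig:
    """3 gestures x 1 object x 6 trials: enough for split/pipeline mechanics."""
    return eg.SyntheticProtocolConfig(
        n_gestures=3, objects_per_gesture=1, trials_per_object=6, seed=7
    )


@pytest.fixture(scope="session")
def small_session(small_config) -> eg.SyntheticSession:
    return eg.generate_session(small_config)


@pytest.fixture(scope="session")
def small_envelopes(small_session):
    envs, mvc = eg.preprocess_session(small_session, eg.PreprocessSettings())
    return envs, mvc


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
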