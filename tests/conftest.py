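"""Shared fixtures: a reference soft-gel cantilever and small protocols."""

import numpy as np
import pytest

from cardiobeam import BeamSpec, MagnetStack, TwitchModel, TwitchProtocol


@pytest.fixture
def beam() -> BeamSpec:
    """Soft-gel reference cantilever: 10 mm x 10 mm free area, 200 um thick,
    12 kPa, incompressible, in water."""
    return BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, nu=0.5, mu=1e-3)


@pytest.fixture
def stack() -> MagnetStack:
    return MagnetStack()  # 7 x (10 mm x 10 mm x 5 mm), 1.2 T


@pytest.fixture
def protocol() -> TwitchProtocol:
    """Five preload levels up to ~1 mm static pre-deflection, short train."""
    return TwitchProtocol(
        preload_levels=(0.0, 1.6e-5, 3.2e-5, 4.8e-5, 6.4e-5), n_twitches=3)


@pytest.fixture
def twitch_model() -> TwitchModel:
    return TwitchModel(F0=1e-5, s_FL=1.0, noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
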