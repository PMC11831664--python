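"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vdw_model():
    from ldpmc import VdwEoS

    return VdwEoS()


@pytest.fixture(scope="session")
def ideal_model():
    from ldpmc import IdealEoS

    return IdealEoS()


@pytest.fixture(scope="session")
def assoc_model():
    from ldpmc import load_model

    return load_model("associating")


@pytest.fixture
def small_config(rng):
    """Random 50-particle configuration in a cubic box, rc-compatible."""
    from ldpmc import Configuration

    box = np.array([4.0, 4.0, 4.0])
    return Configuration(rng.random((50, 3)) * box, box)
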