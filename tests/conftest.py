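import numpy as np
import pytest

from mwtomo.config import DomainConfig


@pytest.fixture
def domain() -> DomainConfig:
    """Full-scale default domain (250 cells at 2 mm)."""
    return DomainConfig()


@pytest.fixture
def small_domain() -> DomainConfig:
    """Reduced 120 mm domain at 2 mm mesh for fast geometry tests."""
    return DomainConfig(
        domain_size=120.0, cell_size=2.0, imaging_radius=40.0, antenna_radius=50.0,
        axis_range=(20.0, 50.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
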