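import numpy as np
import pytest

from sebquant import CoverageConfig, SebollutionSpec, generate_sem_field


@pytest.fixture(scope="session")
def spec():
    return SebollutionSpec()


@pytest.fixture(scope="session")
def cov_cfg():
    return CoverageConfig(pixel_scale=0.2)


@pytest.fixture(scope="session")
def sem_field_8pct():
    """A default SEM field at 8% target coverage, shared across tests."""
    return generate_sem_field(target_coverage=8.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
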