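import numpy as np
import pytest

from seaomega import (ConsumptionScenarioConfig, CountryScenarioConfig,
                      generate_consumption, generate_countries)
from seaomega.datasets import REFERENCE_QUADRANT_COUNTS


@pytest.fixture(scope="session")
def reference_tables():
    """Published six-comparison quadrant counts."""
    return REFERENCE_QUADRANT_COUNTS


@pytest.fixture(scope="session")
def default_records():
    """One default-scenario synthetic country table (n=166, seeded)."""
    return generate_countries(CountryScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def default_profile():
    """One default skewed species-consumption profile (10 species, seeded)."""
    return generate_consumption(ConsumptionScenarioConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
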