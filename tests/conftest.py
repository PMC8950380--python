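import numpy as np
import pandas as pd
import pytest

from synsurv.cohort_io import cohort_to_frame
from synsurv.synth_registry import RegistryConfig, generate_cohort, generate_lifetable


@pytest.fixture(scope="session")
def registry_config():
    return RegistryConfig(n_patients=2000, seed=1)


@pytest.fixture(scope="session")
def cohort(registry_config):
    return generate_cohort(registry_config)


@pytest.fixture(scope="session")
def cohort_frame(cohort):
    return cohort_to_frame(cohort)


@pytest.fixture(scope="session")
def lifetable(registry_config):
    return generate_lifetable(registry_config)


@pytest.fixture
def toy_subset():
    """Four records: deaths at years 2 and 5, censored at 3 and 10."""
    return pd.DataFrame(
        {
            "followup": [2, 3, 5, 10],
            "exitus": ["died", "survived", "died", "survived"],
        }
    )


@pytest.fixture(scope="session")
def null_excess_config():
    """Registry with zero excess hazard and no dropout (EM = 0 ground truth)."""
    return RegistryConfig(
        n_patients=50_000,
        seed=11,
        excess_hazard=((0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
        dropout_hazard=0.0,
        missing_adherence_prob=0.0,
    )
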