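import numpy as np
import pandas as pd
import pytest

from msmimpute.simulator import DGMConfig, WeibullPHSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> DGMConfig:
    return DGMConfig()


@pytest.fixture(scope="session")
def cohort500() -> pd.DataFrame:
    """One default cohort of 500 patients, shared read-only across tests."""
    return simulate_cohort(DGMConfig(n_patients=500, seed=20240501))


@pytest.fixture(scope="session")
def big_cohort() -> pd.DataFrame:
    """A large cohort for distributional checks."""
    return simulate_cohort(DGMConfig(n_patients=40_000, seed=77))


@pytest.fixture()
def tiny_cohort() -> pd.DataFrame:
    """Hand-written six-patient cohort covering all event patterns."""
    return pd.DataFrame(
        {
            "id": [0, 1, 2, 3, 4, 5],
            "z1": [0, 1, 0, 0, 1, 0],
            "z2": [1, 0, 0, 1, 1, 0],
            "aghd_status": [1, 1, 0, 0, 1, 0],
            "aghd_time": [30.0, 15.0, 90.0, 400.0, 60.0, 10.0],
            "rd_status": [1, 0, 1, 0, 1, 1],
            "rd_time": [90.0, 500.0, 90.0, 400.0, 200.0, 10.0],
            "true_aghd_time": [30.0, 15.0, 90.0, 400.0, 60.0, 10.0],
            "true_rd_time": [90.0, 500.0, 90.0, 400.0, 200.0, 10.0],
            "aghd_time_missing": [False] * 6,
            "rd_time_missing": [False] * 6,
        }
    )
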