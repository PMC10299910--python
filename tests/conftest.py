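import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import growthpaths as gp

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return gp.default_params()


@pytest.fixture(scope="session")
def pooled_full(params):
    """One full-size pooled draw (n = 3572) shared across tests."""
    return gp.generate_pooled(params, seed=11)


@pytest.fixture(scope="session")
def pooled_small(params):
    """Reduced pooled draw for structural (non-recovery) tests."""
    return gp.generate_pooled(params, seed=7, scale=0.15)


@pytest.fixture(scope="session")
def fitted_bmiz(pooled_full):
    return gp.GeneralizedPathModel(outcome="bmiz_child").fit(pooled_full)


@pytest.fixture(scope="session")
def fitted_ow(pooled_full):
    return gp.GeneralizedPathModel(outcome="overweight").fit(pooled_full)


@pytest.fixture()
def toy_cutoffs():
    """Synthetic age/sex BMI cutpoint table (NOT the licensed reference)."""
    return pd.DataFrame({
        "age_years": [3.0, 4.0, 5.0, 3.0, 4.0, 5.0],
        "sex": ["male"] * 3 + ["female"] * 3,
        "bmi_cutpoint": [17.8, 17.5, 17.3, 17.6, 17.2, 17.1],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(20260901)
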