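import numpy as np
import pandas as pd
import pytest

from selsurv.cohort import RandomEffectParams, draw_cohort
from selsurv.fixtures import (
    build_synthetic_lifetable,
    load_lifetable_fixture,
    load_target_rates_fixture,
)
from selsurv.mortality import BAND_STARTS, HazardSchedule


@pytest.fixture(scope="session")
def lifetable():
    return load_lifetable_fixture()


@pytest.fixture(scope="session")
def target_rates():
    return load_target_rates_fixture()


@pytest.fixture(scope="session")
def re_params():
    return RandomEffectParams(sigma0=np.sqrt(1 - 0.1**2), sigma1=0.012,
                              sigma2=0.0002, rho01=0.3)


@pytest.fixture(scope="session")
def big_cohort(re_params):
    return draw_cohort(100_000, 0.51, re_params, seed=12345)


def constant_hazard_schedule(rate_per_year: float, beta_u=(0.0, 0.0)) -> HazardSchedule:
    """Schedule with the same per-year hazard in every band, both sexes."""
    lam = np.full((len(BAND_STARTS), 2), np.log(rate_per_year) if rate_per_year > 0 else -30.0)
    return HazardSchedule(log_lambda=lam, beta_u=np.asarray(beta_u))


@pytest.fixture
def flat_schedule():
    return constant_hazard_schedule(0.1)
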