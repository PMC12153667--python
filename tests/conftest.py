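import numpy as np
import pandas as pd
import pytest

import odbatools as ot
from odbatools.synthetic import TrueParameters, make_cohort, simulate_hourly_odba


@pytest.fixture(scope="session")
def default_params():
    return TrueParameters()


@pytest.fixture(scope="session")
def small_study(default_params):
    """12 individuals x 7 days under the default generative parameters."""
    cohort = make_cohort(n_individuals=12, n_days=7, seed=5)
    data, record = simulate_hourly_odba(cohort, default_params, seed=6)
    data["active"] = ot.synthetic.simulate_hourly_activity(
        data, cohort, default_params, seed=7)
    data["night_id"] = ot.ephemeris.assign_nights(data["hour_start"])
    return {"cohort": cohort, "data": data, "record": record}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
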