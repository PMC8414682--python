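import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bloodtrac as bt

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort48():
    """Default 48 LOW / 48 MID desk-scale cohort, seed 1."""
    return bt.simulate(bt.MixtureSpec(rng_seed=1))


@pytest.fixture(scope="session")
def rpkm48(cohort48):
    return bt.rpkm(cohort48.counts, cohort48.transcripts)


@pytest.fixture(scope="session")
def cascade48(cohort48, rpkm48):
    return bt.run_cascade(rpkm48, cohort48.group_map())


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects: equal Treg fractions and unit TRAC fold."""
    spec = bt.MixtureSpec(
        treg_fraction_low=0.04, treg_fraction_mid=0.04, trac_fold=1.0,
        rng_seed=11,
    )
    return bt.simulate(spec)


@pytest.fixture
def toy_matrix():
    """4 transcripts × 4 samples RPKM toy with obvious structure."""
    df = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0, 0.0],
            "s2": [1.0, 4.0, 4.0, 0.0],
            "s3": [1.0, 10.0, 4.0, 0.5],
            "s4": [1.0, 30.0, 4.0, 0.5],
        },
        index=["T1", "T2", "T3", "T4"],
    )
    return bt.ExpressionMatrix(df, "RPKM")
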