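import numpy as np
import pytest

from reaim import synthetic
from reaim.circular import assign_rt_bins


def prepare_forced(trials):
    """On-time, non-catch trials with RT bins attached."""
    df = trials[trials["on_time"] & ~trials["is_catch"]].copy()
    df["rt_bin"] = assign_rt_bins(df["rt_ms"])
    return df


@pytest.fixture(scope="session")
def mr_forced_cohort():
    cfg = synthetic.CohortConfig(n_subjects=32, seed=7)
    return prepare_forced(synthetic.simulate_forced_cohort(cfg))


@pytest.fixture(scope="session")
def rc_forced_cohort():
    params = synthetic.StrategyParams(strategy="RC", t0_ms=225.0)
    cfg = synthetic.CohortConfig(n_subjects=10, strategy_params=params,
                                 seed=2)
    return prepare_forced(synthetic.simulate_forced_cohort(cfg))


@pytest.fixture(scope="session")
def mr_free_cohort():
    cfg = synthetic.CohortConfig(n_subjects=32, seed=7)
    return synthetic.simulate_free_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
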