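import warnings

import pytest

from hemovalid import SimConfig, make_fixture, simulate_experiment
from hemovalid.synthetic_cohort import DeviceErrorModel


@pytest.fixture(scope="session")
def perfect_fixture():
    return make_fixture("perfect")


@pytest.fixture(scope="session")
def biased_fixture():
    return make_fixture("biased")


@pytest.fixture(scope="session")
def noisy_fixture():
    return make_fixture("noisy")


@pytest.fixture(scope="session")
def spiky_fixture():
    return make_fixture("spiky")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition simulated cohort, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_experiment(SimConfig(seed=20260923))


def degenerate_config(seed: int = 0, **kwargs) -> SimConfig:
    """Config whose device channel equals the reference exactly."""
    zeros = {v: 0.0 for v in ("SBP", "DBP", "HR", "CO")}
    cfg = SimConfig(
        device=DeviceErrorModel(
            calibration_offset_sd=dict(zeros),
            proportional_bias=0.0,
            noise_sd=dict(zeros),
            ar1_rho=0.0,
        ),
        spike_prob=0.0,
        dropout_prob=0.0,
        co_missing_prob=0.0,
        seed=seed,
        **kwargs,
    )
    return cfg


@pytest.fixture(scope="session")
def degenerate_cohort():
    return simulate_experiment(degenerate_config(seed=5))
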