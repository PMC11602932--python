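import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from offtreat import ScenarioConfig, SimulationParameters, simulate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def scenario(
    mechanism="DAR",
    disc_c=0.2,
    disc_a=0.2,
    withdrawal=0.5,
    balance="balanced",
    trajectory="return_to_baseline",
    n=375,
    **params,
):
    return ScenarioConfig(
        mechanism=mechanism,
        disc_rate_control=disc_c,
        disc_rate_active=disc_a,
        withdrawal_rate=withdrawal,
        withdrawal_balance=balance,
        sim_params=SimulationParameters(
            n_per_arm=n, off_trajectory=trajectory, **params
        ),
    )


@pytest.fixture
def masked_trial():
    """A moderately incomplete trial exercising every pattern level."""
    return simulate_trial(scenario(mechanism="DNAR", withdrawal=0.5), seed=11)


@pytest.fixture
def complete_trial():
    """Discontinuation present but nobody withdrawn: no missing data."""
    return simulate_trial(scenario(withdrawal=0.0), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
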