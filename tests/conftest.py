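import numpy as np
import pytest

from dfgaba import (
    SyntheticScenario,
    balanced_initial_state,
    kcc2_block_experiment,
    impermeant_anion_experiment,
    steady_state,
    table1_defaults,
)


@pytest.fixture(scope="session")
def params():
    return table1_defaults()


@pytest.fixture(scope="session")
def resting_state(params):
    """Converged resting state of the default model (computed once)."""
    return steady_state(params)


@pytest.fixture(scope="session")
def kcc2_report(params):
    """KCC2-block experiment with its full trajectory (computed once)."""
    return kcc2_block_experiment(params, return_result=True)


@pytest.fixture(scope="session")
def anion_report(params):
    return impermeant_anion_experiment(params, return_result=True)


@pytest.fixture
def fast_scenario():
    """Noiseless scenario with effectively instantaneous voltage kinetics."""
    def make(true_df, **kwargs):
        kwargs.setdefault("tau_on_s", 1e-3)
        kwargs.setdefault("tau_off_s", 1e-3)
        kwargs.setdefault("shot_noise", False)
        return SyntheticScenario(true_df_mV=true_df, **kwargs)

    return make
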