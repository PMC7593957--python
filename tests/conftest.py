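import numpy as np
import pytest

from olivescreen.simulate import (
    SampleTruth,
    SimulationConfig,
    make_default_peak_library,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def library():
    return make_default_peak_library()


@pytest.fixture()
def quiet_config():
    """All stochastic terms off: the forward model becomes deterministic."""
    return SimulationConfig(
        noise_sd_intra=0.0, noise_sd_inter=0.0,
        rt_jitter_sd=0.0, batch_shift=0.0, amp_log_sd=0.0, seed=0,
    )


@pytest.fixture()
def evoo_truth():
    return SampleTruth("EV1", "EVOO", fruity_median=5.0)


@pytest.fixture()
def rancid_loo_truth():
    return SampleTruth("LO1", "LOO", mpd="rancid", defect_median=5.0,
                       fruity_median=0.2)


@pytest.fixture(scope="session")
def small_dataset():
    """90-sample two-batch study set used by several modelling tests."""
    matrix, truths = simulate_dataset(36, 30, 24, n_batches=2, seed=42)
    return matrix, truths


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
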