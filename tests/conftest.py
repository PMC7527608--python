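from dataclasses import replace

import numpy as np
import pytest

from saccadekit.protocol import Phase, SessionProtocol, TrialSpec, make_task_block
from saccadekit.synthetic import SamplingConfig, SimConfig, simulate_session


@pytest.fixture(scope="session")
def clean_sampling():
    return SamplingConfig(warmup_duration_s=0.0, steady_model="frame")


@pytest.fixture(scope="session")
def noise_free_config(clean_sampling):
    return replace(SimConfig().noise_free(), sampling=clean_sampling, settle_after_warmup_s=1.0)


@pytest.fixture(scope="session")
def low_noise_config(clean_sampling):
    return replace(
        SimConfig(), spike_prob=0.0, invalid_prob=0.0,
        sampling=clean_sampling, settle_after_warmup_s=1.0,
    )


def _two_task_protocol(n_pro=10, n_anti=10, seed=11):
    pro = make_task_block("pro", n_pro, seed).phases[0]
    anti_block = make_task_block("anti", n_anti, seed + 1).phases[0]
    anti_trials = tuple(
        TrialSpec(t.trial_index + n_pro, "anti_block", t.task, t.side, t.fore_period_s, False)
        for t in anti_block.trials
    )
    anti = Phase("anti_block", "anti", False, False, anti_trials)
    return SessionProtocol(phases=(pro, anti), seed=seed)


@pytest.fixture(scope="session")
def small_protocol():
    return _two_task_protocol()


@pytest.fixture(scope="session")
def small_session(small_protocol, low_noise_config):
    """A 20-trial mixed session with low noise, simulated once per run."""
    return simulate_session(small_protocol, low_noise_config, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
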