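import numpy as np
import pytest

from momentum_rpe.rpe_models import ModelParams
from momentum_rpe.synthetic_bold import (
    BIPOLAR_LIKE,
    ParticipantGroundTruth,
    SimConfig,
)
from momentum_rpe.task_design import ScheduleConfig, generate_schedule


@pytest.fixture
def small_config():
    """2 blocks x 16 trials: balanced and fast (0.25*8 and 0.75*8 integral)."""
    return ScheduleConfig(n_blocks=2, trials_per_block=16, seed=7)


@pytest.fixture
def small_schedule(small_config):
    return generate_schedule(small_config)


@pytest.fixture
def default_schedule():
    return generate_schedule(ScheduleConfig(seed=11))


@pytest.fixture
def params():
    return ModelParams(eta=0.3, bias_weight=0.5)


@pytest.fixture
def sim():
    return SimConfig()


def make_truth(**kwargs) -> ParticipantGroundTruth:
    """Noiseless ground truth by default; overrides as needed."""
    defaults = dict(
        group=BIPOLAR_LIKE,
        beta_outcome=1.0,
        beta_choice=0.5,
        beta_anticipation=0.4,
        beta_delta=0.7,
        beta_momentum_bias=1.3,
        beta_momentum=0.4,
        gamma0=0.3,
        gamma1=0.2,
        noise_sigma=0.0,
        ar1_rho=0.0,
        drift_amplitude=0.0,
        motion_leak=0.0,
        seed=5,
    )
    defaults.update(kwargs)
    return ParticipantGroundTruth(**defaults)


@pytest.fixture
def noiseless_truth():
    return make_truth()
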