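import math

import pytest

from asrtkit.preprocessing import flag_trials
from asrtkit.synthetic import SimulationConfig, simulate_participant
from asrtkit.task_model import SequenceSpec, classify_triplets


@pytest.fixture
def spec() -> SequenceSpec:
    # the canonical template order 2 - r - 4 - r - 3 - r - 1 - r
    return SequenceSpec((2, 4, 3, 1))


def noiseless_config(**overrides) -> SimulationConfig:
    """Deterministic plant: constant learning effect, no noise, no errors.

    learning_growth_rate=inf makes delta(block) == learning_effect_max for
    every block, so every learning score should equal the programmed delta
    exactly.
    """
    params = dict(
        n_per_group=1,
        noise_sd=0.0,
        error_rate=0.0,
        long_rt_rate=0.0,
        fatigue_slope=0.0,
        skill_gain=0.0,
        learning_effect_max=20.0,
        learning_growth_rate=math.inf,
        learning_online_ramp=0.0,
        offline_recovery=0.0,
        seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def flagged_participant(config: SimulationConfig, group="fixed_15", pid="p1"):
    """Simulate one participant and return QC-annotated trials."""
    record = simulate_participant(config, group, pid)
    classified = classify_triplets(record.trials, record.sequence)
    return flag_trials(classified)
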