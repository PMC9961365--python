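"""Synthetic ASRT cohorts and generation-task (PDP) runs.

A generative stand-in for a real behavioral cohort, with the statistical
structure the analysis assumes: block-wise general speedup, a growing
high-vs-low-probability RT gap (statistical learning), within-block slowing
(fatigue) relieved by the between-block rests, ~9% incorrect responses, a
small rate of very slow (>1000 ms) responses, and group-specific rest
schedules (fixed 15 s, fixed 30 s, or self-paced with a heavy-tailed
lognormal duration).

The reaction-time plant for a trial in block ``b``, within-block bin ``k``
(1-5), that is the third element of a high-probability triplet or not
(``h`` in {0,1}) is::

    RT = baseline - skill(b) + fatigue(b, k) - delta(b, k) * h + eps

with ``skill(b) = skill_gain * (1 - exp(-skill_growth_rate * b))``,
``delta(b, k) = learning_effect_max * (1 - exp(-learning_growth_rate * b))
+ learning_online_ramp * (k - 1) / 4``, ``eps ~ Normal(0, noise_sd)``, and
RTs floored at 150 ms. Fatigue accumulates at ``fatigue_slope`` ms per bin;
each rest clears up to ``offline_recovery`` ms of the accumulated fatigue
(with the defaults the rests clear it entirely). Setting
``learning_growth_rate`` to ``math.inf`` yields a constant delta, the
"noiseless plant" used by the exactness tests when noise is also zeroed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .task_model import (
    InvalidConfigurationError,
    SequenceSpec,
    classify_triplets,
    enumerate_sequences,
    generate_stream,
)

GROUPS = ("self_paced", "fixed_15", "fixed_30")

RT_FLOOR_MS = 150.0
TRIALS_PER_BIN = 16


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: 25 blocks of 80 trials, a ~450 ms
    baseline with 60 ms trial noise, an asymptotic 25 ms statistical-learning
    effect, 9% errors, 0.24% very long RTs, and self-paced rests whose
    lognormal parameters reproduce a 16.67 s mean and 10.58 s median.
    """

    n_per_group: int = Field(default=30, ge=1)
    groups: tuple[str, ...] = GROUPS
    n_blocks: int = Field(default=25, ge=2)
    trials_per_block: int = Field(default=80, gt=0)
    baseline_rt: float = Field(default=450.0, ge=0)
    skill_gain: float = Field(default=60.0, ge=0)
    skill_growth_rate: float = Field(default=0.12, ge=0)
    learning_effect_max: float = Field(default=25.0, ge=0)
    learning_growth_rate: float = Field(default=0.15, ge=0)
    learning_online_ramp: float = 0.0
    fatigue_slope: float = Field(default=3.0, ge=0)
    offline_recovery: float = Field(default=20.0, ge=0)
    noise_sd: float = Field(default=60.0, ge=0)
    error_rate: float = Field(default=0.09, ge=0, le=1)
    long_rt_rate: float = Field(default=0.0024, ge=0, le=1)
    selfpaced_rest_log_mu: float = math.log(10.58)
    selfpaced_rest_log_sigma: float = Field(default=0.954, ge=0)
    late_starter_rate: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0

    @field_validator("groups")
    @classmethod
    def _known_groups(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        bad = set(v) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        return v


@dataclass
class ParticipantRecord:
    """All blocks of one simulated (or loaded) participant."""

    participant_id: str
    group: str
    age: float
    sequence: SequenceSpec
    trials: pd.DataFrame
    rest_durations: list[float]
    block_start_latencies: list[float]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trial table including per-block metadata."""
        df = self.trials.copy()
        df.insert(0, "participant_id", self.participant_id)
        df.insert(1, "group", self.group)
        df.insert(2, "age", self.age)
        df.insert(3, "sequence", self.sequence.to_string())
        rest = dict(zip(range(2, len(self.rest_durations) + 2), self.rest_durations))
        df["rest_before_s"] = df["block"].map(rest)
        lat = dict(zip(range(1, len(self.block_start_latencies) + 1),
                       self.block_start_latencies))
        df["block_start_latency_ms"] = df["block"].map(lat)
        return df


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    # stable sub-stream per (cohort seed, id); crc32 keeps it text-derived
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(participant_id.encode())])
    )


def _learning_curve(cfg: SimulationConfig, blocks: np.ndarray) -> np.ndarray:
    rate = cfg.learning_growth_rate
    with np.errstate(over="ignore"):
        return cfg.learning_effect_max * (1.0 - np.exp(-rate * blocks))


def simulate_participant(
    config: SimulationConfig, group: str, participant_id: str
) -> ParticipantRecord:
    """Simulate one participant's full ASRT session.

    Deterministic in ``(config.seed, participant_id)``; the same call twice
    returns identical records.
    """
    if group not in GROUPS:
        raise InvalidConfigurationError(f"unknown group {group!r}")
    rng = _participant_rng(config.seed, participant_id)

    spec = enumerate_sequences()[rng.integers(0, 24)]
    stream = generate_stream(
        spec, config.n_blocks, config.trials_per_block, rng
    )
    stream = classify_triplets(stream, spec)
    n = len(stream)
    block = stream["block"].to_numpy()
    trial = stream["trial"].to_numpy()
    is_high = (stream["triplet"] == "high").to_numpy()
    bin_idx = (trial - 1) // TRIALS_PER_BIN  # 0-based bin

    bins_per_block = max(1, config.trials_per_block // TRIALS_PER_BIN)
    # fatigue carried over a rest: each rest clears up to offline_recovery ms
    carry = np.zeros(config.n_blocks)
    per_block_gain = config.fatigue_slope * (bins_per_block - 1)
    for b in range(1, config.n_blocks):
        carry[b] = max(0.0, carry[b - 1] + per_block_gain - config.offline_recovery)

    blocks = np.arange(1, config.n_blocks + 1)
    with np.errstate(over="ignore"):
        skill = config.skill_gain * (1.0 - np.exp(-config.skill_growth_rate * blocks))
    delta_base = _learning_curve(config, blocks)

    rt = (
        config.baseline_rt
        - skill[block - 1]
        + carry[block - 1]
        + config.fatigue_slope * bin_idx
        - (delta_base[block - 1] + config.learning_online_ramp * bin_idx / 4.0)
        * is_high
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    rt = np.maximum(rt, RT_FLOOR_MS)
    long_mask = rng.random(n) < config.long_rt_rate
    rt[long_mask] = rng.uniform(1000.0, 1500.0, size=int(long_mask.sum()))

    correct = rng.random(n) >= config.error_rate
    position = stream["position"].to_numpy()
    # an incorrect response is any of the three other keys
    wrong = (position + rng.integers(1, 4, size=n) - 1) % 4 + 1
    response = np.where(correct, position, wrong)

    trials = stream.drop(columns=["triplet", "is_trill", "is_repetition"])
    trials["response"] = response.astype(int)
    trials["rt_ms"] = np.round(rt, 3)
    trials["correct"] = correct.astype(int)

    if group == "fixed_15":
        rests = [15.0] * (config.n_blocks - 1)
    elif group == "fixed_30":
        rests = [30.0] * (config.n_blocks - 1)
    else:
        rests = list(
            np.round(
                rng.lognormal(
                    config.selfpaced_rest_log_mu,
                    config.selfpaced_rest_log_sigma,
                    size=config.n_blocks - 1,
                ),
                3,
            )
        )

    late = rng.random() < config.late_starter_rate
    if late:
        latencies = rng.normal(1800.0, 200.0, size=config.n_blocks)
    else:
        latencies = rng.normal(500.0, 150.0, size=config.n_blocks)
    latencies = list(np.round(np.maximum(latencies, 0.0), 1))

    age = float(rng.integers(19, 35))
    return ParticipantRecord(
        participant_id=participant_id,
        group=group,
        age=age,
        sequence=spec,
        trials=trials,
        rest_durations=rests,
        block_start_latencies=latencies,
    )


def simulate_cohort(config: SimulationConfig) -> list[ParticipantRecord]:
    """Simulate ``n_per_group`` participants for each requested group."""
    records = []
    for group in config.groups:
        for i in range(config.n_per_group):
            pid = f"{group}_{i + 1:03d}"
            records.append(simulate_participant(config, group, pid))
    return records


def cohort_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Concatenate participant records into one tidy trial table."""
    return pd.concat([r.to_frame() for r in records], ignore_index=True)


def simulate_pdp_runs(
    spec: SequenceSpec,
    condition: str,
    n_runs: int,
    bias: float,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    presses_per_run: int = 24,
):
    """Simulate generation-task runs of key presses.

    Each press follows the learned pattern successor of the press two back
    with probability ``bias``, and is uniform over the four keys otherwise;
    ``bias=0`` is pure chance pressing (25% high-probability triplets),
    ``bias=1`` makes every classifiable press complete a high-probability
    triplet.
    """
    from .pdp import PDPRun  # local import avoids a cycle

    if n_runs < 1:
        raise InvalidConfigurationError("n_runs must be >= 1")
    if not 0.0 <= bias <= 1.0:
        raise InvalidConfigurationError("bias must lie in [0, 1]")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    succ = spec.successor_map
    runs = []
    for r in range(n_runs):
        presses = list(rng.integers(1, 5, size=2))
        for _ in range(presses_per_run - 2):
            if rng.random() < bias:
                presses.append(succ[presses[-2]])
            else:
                presses.append(int(rng.integers(1, 5)))
        runs.append(
            PDPRun(
                participant_id=participant_id,
                condition=condition,
                run_index=r + 1,
                presses=[int(p) for p in presses],
            )
        )
    return runs
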