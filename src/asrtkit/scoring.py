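"""Unit-of-five-blocks learning scores and general-skill RTs.

Learning blocks are organized into units of five consecutive blocks
(1-5, 6-10, 11-15, 16-20, 21-25). Within a unit, over the eligible trials
(not excluded by QC, triplet classifiable):

* statistical-learning score = median RT(low) - median RT(high), in ms;
* standardized learning score = learning score / mean RT of the unit
  (dimensionless; controls for baseline-speed differences between groups);
* general-skill RT = median RT of all eligible trials regardless of
  triplet category.

Medians are pooled over the whole unit, not averaged per block. A unit with
no eligible high or no eligible low trials yields NaN scores, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_model import InvalidConfigurationError


@dataclass
class UnitScore:
    participant_id: str
    unit_index: int
    median_rt_high: float
    median_rt_low: float
    learning_score: float
    mean_rt: float
    standardized_learning: float
    general_skill_rt: float
    n_high: int
    n_low: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.learning_score))


def unit_partition(n_blocks: int, unit_size: int = 5) -> list[range]:
    """Contiguous, disjoint block-index ranges covering 1..n_blocks."""
    if unit_size <= 0 or n_blocks % unit_size != 0:
        raise InvalidConfigurationError(
            f"n_blocks ({n_blocks}) must be divisible by unit_size ({unit_size})"
        )
    return [
        range(start, start + unit_size)
        for start in range(1, n_blocks + 1, unit_size)
    ]


def eligible_trials(flagged: pd.DataFrame) -> pd.DataFrame:
    """Trials entering RT statistics: not excluded and triplet-classifiable."""
    return flagged[~flagged["excluded"]]


def score_unit(
    unit_trials: pd.DataFrame, participant_id: str = "", unit_index: int = 0
) -> UnitScore:
    """Score one unit from its flagged trials (pooled medians)."""
    elig = eligible_trials(unit_trials)
    rt = pd.to_numeric(elig["rt_ms"], errors="coerce")
    high = rt[elig["triplet"] == "high"].dropna()
    low = rt[elig["triplet"] == "low"].dropna()
    all_rt = rt.dropna()
    if len(high) == 0 or len(low) == 0:
        med_h = float(high.median()) if len(high) else np.nan
        med_l = float(low.median()) if len(low) else np.nan
        return UnitScore(
            participant_id, unit_index, med_h, med_l,
            np.nan, float(all_rt.mean()) if len(all_rt) else np.nan,
            np.nan, float(all_rt.median()) if len(all_rt) else np.nan,
            len(high), len(low),
        )
    med_h = float(high.median())
    med_l = float(low.median())
    learning = med_l - med_h
    mean_rt = float(all_rt.mean())
    return UnitScore(
        participant_id=participant_id,
        unit_index=unit_index,
        median_rt_high=med_h,
        median_rt_low=med_l,
        learning_score=learning,
        mean_rt=mean_rt,
        standardized_learning=learning / mean_rt if mean_rt else np.nan,
        general_skill_rt=float(all_rt.median()),
        n_high=len(high),
        n_low=len(low),
    )


def score_participant(
    flagged: pd.DataFrame,
    n_blocks: int = 25,
    unit_size: int = 5,
    participant_id: str | None = None,
) -> list[UnitScore]:
    """One :class:`UnitScore` per unit, in order, for one participant.

    ``flagged`` holds one participant's QC-annotated learning-block trials.
    """
    present = set(flagged["block"].unique())
    expected = set(range(1, n_blocks + 1))
    if present != expected:
        raise InvalidConfigurationError(
            f"expected blocks 1..{n_blocks}, got {sorted(present)}"
        )
    if participant_id is None:
        participant_id = (
            str(flagged["participant_id"].iloc[0])
            if "participant_id" in flagged
            else ""
        )
    scores = []
    for i, block_range in enumerate(unit_partition(n_blocks, unit_size), start=1):
        unit_trials = flagged[flagged["block"].isin(block_range)]
        scores.append(score_unit(unit_trials, participant_id, i))
    return scores


def unit_scores_frame(per_participant: dict[str, list[UnitScore]],
                      groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy unit-score table (one row per participant x unit)."""
    rows = []
    for pid, scores in per_participant.items():
        for s in scores:
            rows.append(
                {
                    "participant_id": pid,
                    "group": (groups or {}).get(pid, ""),
                    "unit": s.unit_index,
                    "median_rt_high": s.median_rt_high,
                    "median_rt_low": s.median_rt_low,
                    "learning_score": s.learning_score,
                    "mean_rt": s.mean_rt,
                    "standardized_learning": s.standardized_learning,
                    "general_skill_rt": s.general_skill_rt,
                    "n_high": s.n_high,
                    "n_low": s.n_low,
                }
            )
    return pd.DataFrame(rows)
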