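"""Trial- and participant-level quality control.

Trial-level rules (each computed independently from the raw trial, so the
flags are order-independent and idempotent): incorrect responses, trills
(x-y-x), repetitions (x-x-x), RTs strictly above 1000 ms, and the first two
trials of each block (no classifiable triplet). A trial may carry several
reasons; the exclusion report counts each reason separately and the overlap-
aware total once.

Participant-level rules: overall ASRT accuracy below 80%; block-start
latency above 1500 ms in at least five blocks; mean RT of blocks' first
trials above 1000 ms; age above 35 years. Exclusions that depend on tasks
outside the ASRT session (n-back performance, restarts, prior participation)
are accepted as caller-supplied metadata flags, never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

logger = logging.getLogger(__name__)

TRIAL_EXCLUSION_REASONS = (
    "incorrect",
    "trill",
    "repetition",
    "long_rt",
    "unclassifiable",
)


class PipelineOrderError(RuntimeError):
    """Raised when a stage runs before its prerequisites (e.g. QC before
    triplet classification)."""


class QCCriteria(BaseModel):
    """Thresholds of the participant- and trial-level rules."""

    accuracy_min: float = Field(default=0.80, gt=0)
    rt_max_ms: float = Field(default=1000.0, gt=0)
    latency_limit_ms: float = Field(default=1500.0, gt=0)
    latency_block_min: int = Field(default=5, gt=0)
    first_trial_rt_max_ms: float = Field(default=1000.0, gt=0)
    age_max: float = Field(default=35.0, gt=0)


def flag_trials(trials: pd.DataFrame, criteria: QCCriteria | None = None) -> pd.DataFrame:
    """Annotate each trial with its exclusion reasons.

    Requires triplet classification columns (``triplet``, ``is_trill``,
    ``is_repetition``). Adds one boolean column per reason
    (``excl_<reason>``) and ``excluded`` (true iff any reason applies).
    Never mutates RTs or positions. The RT rule is strict: rt == 1000 ms is
    kept.
    """
    criteria = criteria or QCCriteria()
    missing = {"triplet", "is_trill", "is_repetition"} - set(trials.columns)
    if missing:
        raise PipelineOrderError(
            f"triplets must be classified before QC (missing columns: {sorted(missing)})"
        )
    out = trials.copy()
    rt = pd.to_numeric(out["rt_ms"], errors="coerce")
    out["excl_incorrect"] = out["correct"].astype(int) == 0
    out["excl_trill"] = out["is_trill"].astype(bool)
    out["excl_repetition"] = out["is_repetition"].astype(bool)
    out["excl_long_rt"] = (rt > criteria.rt_max_ms).fillna(False)
    out["excl_unclassifiable"] = out["triplet"] == "unclassifiable"
    out["excluded"] = np.logical_or.reduce(
        [out[f"excl_{r}"].to_numpy() for r in TRIAL_EXCLUSION_REASONS]
    )
    return out


def participant_filter(
    record, criteria: QCCriteria | None = None
) -> tuple[bool, list[str]]:
    """Apply the participant-level exclusion rules.

    ``record`` may be a :class:`~asrtkit.synthetic.ParticipantRecord` or a
    single participant's tidy trial frame. Returns ``(kept, reasons)``;
    latency-based rules are skipped with a logged warning when no latencies
    are present.
    """
    criteria = criteria or QCCriteria()
    if isinstance(record, pd.DataFrame):
        trials = record
        age = float(trials["age"].iloc[0]) if "age" in trials else np.nan
        if "block_start_latency_ms" in trials:
            latencies = (
                trials.groupby("block")["block_start_latency_ms"].first().to_numpy()
            )
        else:
            latencies = np.array([])
        pid = trials["participant_id"].iloc[0] if "participant_id" in trials else "?"
    else:
        trials = record.trials
        age = record.age
        latencies = np.asarray(record.block_start_latencies, dtype=float)
        pid = record.participant_id

    reasons: list[str] = []
    learning = trials[trials["block"] >= 1]  # practice blocks are block <= 0
    accuracy = learning["correct"].astype(int).mean() if len(learning) else np.nan
    if np.isfinite(accuracy) and accuracy < criteria.accuracy_min:
        reasons.append("accuracy")

    latencies = latencies[np.isfinite(latencies)] if latencies.size else latencies
    if latencies.size == 0:
        logger.warning("participant %s: no block-start latencies; latency rule skipped", pid)
    elif (latencies > criteria.latency_limit_ms).sum() >= criteria.latency_block_min:
        reasons.append("late_block_start")

    first_rts = pd.to_numeric(
        learning.loc[learning["trial"] == 1, "rt_ms"], errors="coerce"
    ).dropna()
    if len(first_rts) and first_rts.mean() > criteria.first_trial_rt_max_ms:
        reasons.append("slow_first_trials")

    if np.isfinite(age) and age > criteria.age_max:
        reasons.append("age")

    return (len(reasons) == 0, reasons)


@dataclass
class ExclusionReport:
    """Auditable summary of trial- and participant-level exclusions."""

    n_trials: int
    reason_counts: dict[str, int]
    reason_percentages: dict[str, float]
    n_excluded: int
    percent_excluded: float
    participants: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "reason_counts": self.reason_counts,
            "reason_percentages": self.reason_percentages,
            "n_excluded": self.n_excluded,
            "percent_excluded": self.percent_excluded,
            "participants": self.participants,
        }

    def to_text(self) -> str:
        lines = [f"Trials: {self.n_trials}"]
        for r in TRIAL_EXCLUSION_REASONS:
            lines.append(
                f"  {r:<15} {self.reason_counts[r]:>8}  ({self.reason_percentages[r]:.2f}%)"
            )
        lines.append(
            f"  total excluded  {self.n_excluded:>8}  ({self.percent_excluded:.2f}%)"
            " (reasons overlap; the total is not their sum)"
        )
        n_removed = sum(1 for v in self.participants.values() if v["status"] == "excluded")
        lines.append(f"Participants: {len(self.participants)} ({n_removed} excluded)")
        for pid, info in self.participants.items():
            if info["status"] == "excluded":
                lines.append(f"  {pid}: excluded ({', '.join(info['reasons'])})")
        return "\n".join(lines)


def build_exclusion_report(
    flagged: pd.DataFrame,
    participant_status: dict[str, tuple[bool, list[str]]] | None = None,
) -> ExclusionReport:
    """Count exclusions per reason and overall (overlap-aware)."""
    n = len(flagged)
    counts = {r: int(flagged[f"excl_{r}"].sum()) for r in TRIAL_EXCLUSION_REASONS}
    pcts = {r: (100.0 * c / n if n else 0.0) for r, c in counts.items()}
    n_excl = int(flagged["excluded"].sum())
    participants = {}
    for pid, (kept, reasons) in (participant_status or {}).items():
        participants[pid] = {
            "status": "kept" if kept else "excluded",
            "reasons": reasons,
        }
    return ExclusionReport(
        n_trials=n,
        reason_counts=counts,
        reason_percentages=pcts,
        n_excluded=n_excl,
        percent_excluded=100.0 * n_excl / n if n else 0.0,
        participants=participants,
    )
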