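"""Process-dissociation (generation task) scoring.

After the ASRT session, participants generate sequences on the same four
keys, first trying to reproduce the learned sequence (inclusion) and then
trying to avoid it (exclusion). Each run is up to 24 presses (three rounds
of the eight-element sequence). Knowledge is quantified as the percentage
of classifiable presses (the 3rd onward within a run; runs are never
concatenated) that complete a high-probability triplet under the
participant's sequence, against the 25% level expected from uniform
pressing. Runs dominated by trills/repetitions (>50% of classifiable
presses, strictly) are removed before scoring; trill/repetition presses in
kept runs stay in both numerator candidates and denominator, preserving the
25% chance anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import InsufficientDataError, TTestResult, one_sample_t
from .task_model import MalformedDataError, SequenceSpec, classify_presses

CHANCE_PERCENT = 25.0


@dataclass
class PDPRun:
    """One generation run under inclusion or exclusion instruction."""

    participant_id: str
    condition: str  # inclusion | exclusion
    run_index: int
    presses: list[int]
    kept: bool = field(default=True)

    def __post_init__(self) -> None:
        if len(self.presses) == 0:
            raise MalformedDataError("a PDP run must contain at least one press")
        if any(p not in (1, 2, 3, 4) for p in self.presses):
            raise MalformedDataError(f"presses must lie in 1..4: {self.presses}")


def _press_labels(run: PDPRun, spec: SequenceSpec) -> pd.DataFrame:
    labels = classify_presses(np.asarray(run.presses), spec)
    return labels[labels["triplet"] != "unclassifiable"]


def filter_runs(runs: list[PDPRun], spec: SequenceSpec | None = None) -> list[PDPRun]:
    """Mark runs where >50% of classifiable presses are trills/repetitions.

    Trill/repetition classification does not depend on the sequence, but a
    spec may be passed for interface symmetry. Press content is never
    altered; only ``kept`` is set. Exactly 50% is kept (strict rule).
    """
    spec = spec or SequenceSpec((1, 2, 3, 4))
    out = []
    for run in runs:
        classifiable = _press_labels(run, spec)
        n = len(classifiable)
        bad = int((classifiable["is_trill"] | classifiable["is_repetition"]).sum())
        kept = not (n > 0 and bad / n > 0.5)
        out.append(
            PDPRun(run.participant_id, run.condition, run.run_index,
                   list(run.presses), kept)
        )
    return out


def fully_removed_participants(runs: list[PDPRun]) -> set[tuple[str, str]]:
    """(participant, condition) pairs with zero kept runs."""
    frame = pd.DataFrame(
        [(r.participant_id, r.condition, r.kept) for r in runs],
        columns=["pid", "condition", "kept"],
    )
    any_kept = frame.groupby(["pid", "condition"])["kept"].any()
    return set(any_kept[~any_kept].index)


def high_prob_ratio(runs: list[PDPRun], spec: SequenceSpec) -> float:
    """Percentage of classifiable presses forming high-probability triplets.

    Pooled over the kept runs passed in (callers pass one participant's
    runs of one condition). A 24-press run contributes 22 classifiable
    presses. Returns NaN when no runs are kept.
    """
    n_high = 0
    n_classifiable = 0
    for run in runs:
        if not run.kept:
            continue
        labels = _press_labels(run, spec)
        n_classifiable += len(labels)
        n_high += int((labels["triplet"] == "high").sum())
    if n_classifiable == 0:
        return float("nan")
    return 100.0 * n_high / n_classifiable


def chance_test(ratios, chance: float = CHANCE_PERCENT) -> TTestResult:
    """One-sample t-test of per-participant ratios against the chance level."""
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise InsufficientDataError("chance_test needs ratios from >= 2 participants")
    return one_sample_t(x, chance)


def score_pdp_table(table: pd.DataFrame, specs: dict[str, SequenceSpec]) -> pd.DataFrame:
    """Score a tidy PDP press table.

    ``table`` columns: participant_id, condition, run_index, press_index,
    key. ``specs`` maps participant to their sequence. Returns one row per
    (participant, condition) with the high-probability ratio over kept runs.
    """
    rows = []
    for (pid, condition), sub in table.groupby(["participant_id", "condition"]):
        runs = [
            PDPRun(pid, condition, int(run_idx),
                   list(run.sort_values("press_index")["key"].astype(int)))
            for run_idx, run in sub.groupby("run_index")
        ]
        runs = filter_runs(runs)
        ratio = high_prob_ratio(runs, specs[pid])
        rows.append(
            {
                "participant_id": pid,
                "condition": condition,
                "n_runs": len(runs),
                "n_kept": sum(r.kept for r in runs),
                "high_prob_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
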