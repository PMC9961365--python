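"""Decompose learning into online (within-block) and offline (across-rest)
changes and test each against zero per group.

Positive mean online and negative mean offline statistical-learning changes
indicate gains built up during practice that partly reset over the rests;
for general skill, within-block slowing (positive online) that recovers
across rests (negative offline) is the fatigue signature.
"""

from pathlib import Path

import pandas as pd

from asrtkit.dynamics import change_scores, change_scores_frame, summarize_changes

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    flagged = pd.read_csv(SCRATCH / "trials_flagged.csv")
    groups = flagged.groupby("participant_id")["group"].first().to_dict()
    css = [
        change_scores(sub, pid) for pid, sub in flagged.groupby("participant_id")
    ]
    frame = change_scores_frame(css, groups)
    frame.to_csv(RESULTS / "changes.csv", index=False, lineterminator="\n")
    summary = summarize_changes(frame)
    summary.to_csv(RESULTS / "changes_summary.csv", index=False, lineterminator="\n")
    print("one-sample t-tests of mean change scores vs 0, by group:")
    print(summary.round(3).to_string(index=False))
    sl = summary[summary["measure"].isin(["mean_online_sl", "mean_offline_sl"])]
    signs = sl.groupby("measure")["mean"].mean()
    print(
        f"\ncohort-level pattern: online_sl {signs['mean_online_sl']:+.2f} ms, "
        f"offline_sl {signs['mean_offline_sl']:+.2f} ms "
        "(within-block gain, across-rest forgetting)"
    )


if __name__ == "__main__":
    main()
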