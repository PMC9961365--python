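"""Compute unit-of-five-blocks learning scores and test their time course.

For each kept participant: statistical-learning score (median low-prob RT
minus median high-prob RT), its standardized version, and general-skill
median RT per unit of five blocks. A mixed-design ANOVA (unit x group)
checks whether learning grows over units and differs between rest groups.
"""

import json
from pathlib import Path

import pandas as pd

from asrtkit.inference import group_descriptives, mixed_anova_contract
from asrtkit.scoring import score_participant, unit_scores_frame

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    flagged = pd.read_csv(SCRATCH / "trials_flagged.csv")
    groups = flagged.groupby("participant_id")["group"].first().to_dict()
    scores = {
        pid: score_participant(sub, 25, 5, pid)
        for pid, sub in flagged.groupby("participant_id")
    }
    units = unit_scores_frame(scores, groups)
    units.to_csv(RESULTS / "units.csv", index=False, lineterminator="\n")

    final = units[units["unit"] == 5]
    desc = group_descriptives(
        {g: sub["learning_score"].to_numpy() for g, sub in final.groupby("group")}
    )
    print("final-unit (blocks 21-25) learning score by group (ms):")
    print(desc.round(2).to_string(index=False))

    aov = mixed_anova_contract(
        units.dropna(subset=["learning_score"]),
        dv="learning_score", within="unit", between="group",
    )
    aov.to_csv(RESULTS / "learning_anova.csv", index=False, lineterminator="\n")
    print("\nmixed ANOVA on learning scores (unit x group):")
    print(aov[["effect", "F", "df1", "df2", "p", "np2"]].round(4).to_string(index=False))

    (RESULTS / "final_unit_learning.json").write_text(
        json.dumps(desc.to_dict(orient="records"), indent=2, default=float) + "\n"
    )


if __name__ == "__main__":
    main()
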