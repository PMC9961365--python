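# asrtkit

Analysis pipeline for **alternating serial reaction time (ASRT)** studies of
implicit statistical learning and its rapid, rest-period consolidation —
plus a synthetic cohort simulator so the entire pipeline is testable
end-to-end without any participant data.

## The task and the statistics it yields

In the ASRT task a stimulus appears in one of four positions (1–4, left to
right) and participants respond with the matching key. Hidden from them,
every other trial follows a fixed four-element cycle (e.g. `2 – r – 4 – r –
3 – r – 1 – r`, `r` random), one of 4! = 24 possible sequences. Each trial
is the third element of a *triplet*: it is **high-probability** when its
position equals the pattern successor of the position two trials back
(62.5% of trials = 0.5 + 0.5·¼), **low-probability** otherwise (37.5%).

From trial-level reaction times the package computes, per participant:

- **statistical learning** per unit of five blocks:
  `SL = median RT(low) − median RT(high)`, standardized as `SL / mean RT`;
- **general skill**: median RT per unit regardless of triplet type;
- **online/offline decomposition**: each 80-trial block splits into five
  16-trial bins with a learning score per bin;
  `online(b) = bin5(b) − bin1(b)` (25 scores),
  `offline(b) = bin1(b+1) − bin5(b)` (24 scores), and their means — the
  micro-online gains and micro-offline changes around the between-block
  rests;
- **generation-task (PDP) awareness**: the percentage of generated
  key-press triplets that are high-probability, against the 25% chance
  level, after removing runs dominated (>50%) by trills (x-y-x) and
  repetitions (x-x-x).

Quality control follows the standard rules: drop incorrect trials, trills,
repetitions, RTs > 1000 ms and the two unclassifiable trials per block;
exclude participants below 80% accuracy, with block-start latencies
> 1500 ms in ≥ 5 blocks, mean first-trial RT > 1000 ms, or age > 35.

## Worked example

```python
from asrtkit import (SequenceSpec, generate_stream, classify_triplets,
                     SimulationConfig, simulate_participant,
                     flag_trials, score_participant)

spec = SequenceSpec((2, 4, 3, 1))
rec = simulate_participant(SimulationConfig(seed=3), "self_paced", "p1")
flagged = flag_trials(classify_triplets(rec.trials, rec.sequence))
for unit in score_participant(flagged, n_blocks=25):
    print(unit.unit_index, round(unit.learning_score, 1),
          round(unit.general_skill_rt, 1))
```

prints one row per unit of five blocks — learning score (ms) and
general-skill median RT (ms):

```
1 2.1 434.9
2 14.6 406.0
3 30.1 396.7
4 42.1 380.3
5 14.5 382.2
```

a single simulated participant: the high/low RT gap grows from ~2 ms to
tens of ms across units (noisy at n = 1, as real participants are) while
overall RT drops ~50 ms.

The numbered scripts under `analysis/` run the full study-shaped analysis
on a 60-participant synthetic cohort (three rest groups):
`01_simulate_cohort.py` → `02_quality_control.py` → `03_learning_scores.py`
→ `04_online_offline.py` → `05_pdp_awareness.py`, writing their tables to
`results/`. The same stages are available as a CLI
(`asrtkit simulate|qc|score|dynamics|pdp|run`).

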