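"""Online/offline change-score decomposition.

Each 80-trial block is divided into five bins of 16 consecutive trial
positions (1-16, 17-32, 33-48, 49-64, 65-80; exclusions happen inside bins,
never by shifting bin boundaries). Per bin we compute a statistical-learning
score (median low-probability RT minus median high-probability RT over
eligible trials) and a general-skill score (median RT of all eligible
trials). Then, per participant:

* online(b)  = score(bin 5 of block b) - score(bin 1 of block b)
  -- the within-block change; 25 values for 25 blocks;
* offline(b) = score(bin 1 of block b+1) - score(bin 5 of block b)
  -- the across-rest change; 24 values.

Sign conventions: positive online_sl is a within-block learning gain;
negative offline_sl is forgetting over the rest; positive online_gs is
within-block RT slowing; negative offline_gs is an RT drop across the rest.
A bin with no eligible high or low trials yields a missing bin score; the
change scores touching it are missing, and the per-participant means are
taken over available entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_model import InvalidConfigurationError
from .inference import one_sample_t

TRIALS_PER_BIN = 16
BINS_PER_BLOCK = 5
BLOCK_LENGTH = TRIALS_PER_BIN * BINS_PER_BLOCK


@dataclass
class ChangeScores:
    """Per-participant online/offline change vectors (ms)."""

    participant_id: str
    online_sl: np.ndarray   # length n_blocks
    offline_sl: np.ndarray  # length n_blocks - 1
    online_gs: np.ndarray
    offline_gs: np.ndarray

    @property
    def mean_online_sl(self) -> float:
        return float(np.nanmean(self.online_sl))

    @property
    def mean_offline_sl(self) -> float:
        return float(np.nanmean(self.offline_sl))

    @property
    def mean_online_gs(self) -> float:
        return float(np.nanmean(self.online_gs))

    @property
    def mean_offline_gs(self) -> float:
        return float(np.nanmean(self.offline_gs))


def bin_partition(block_trials: pd.DataFrame) -> list[pd.DataFrame]:
    """Split one block's trials into 5 bins by raw within-block position."""
    n_positions = block_trials["trial"].max()
    if n_positions != BLOCK_LENGTH or len(block_trials) != BLOCK_LENGTH:
        raise InvalidConfigurationError(
            f"bin partition requires {BLOCK_LENGTH}-trial blocks, got {len(block_trials)}"
        )
    b = (block_trials["trial"] - 1) // TRIALS_PER_BIN
    return [block_trials[b == k] for k in range(BINS_PER_BLOCK)]


def bin_scores(flagged: pd.DataFrame) -> pd.DataFrame:
    """Per (block, bin) learning score and median RT for one participant.

    ``flagged`` is one participant's QC-annotated trial table. Returns a
    frame with columns ``block``, ``bin`` (1-5), ``learning_score``,
    ``median_rt`` (NaN where undefined).
    """
    lengths = flagged.groupby("block")["trial"].max()
    bad = lengths[lengths != BLOCK_LENGTH]
    if len(bad):
        raise InvalidConfigurationError(
            f"blocks must have {BLOCK_LENGTH} trials; offending blocks: {list(bad.index)}"
        )
    df = flagged[~flagged["excluded"]].copy()
    df["bin"] = (df["trial"] - 1) // TRIALS_PER_BIN + 1
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    df = df.assign(_rt=rt)

    grid = pd.MultiIndex.from_product(
        [sorted(flagged["block"].unique()), range(1, BINS_PER_BLOCK + 1)],
        names=["block", "bin"],
    )
    med_high = (
        df[df["triplet"] == "high"].groupby(["block", "bin"])["_rt"].median()
    )
    med_low = df[df["triplet"] == "low"].groupby(["block", "bin"])["_rt"].median()
    med_all = df.groupby(["block", "bin"])["_rt"].median()

    out = pd.DataFrame(index=grid)
    out["learning_score"] = med_low.reindex(grid) - med_high.reindex(grid)
    out["median_rt"] = med_all.reindex(grid)
    return out.reset_index()


def _changes(series: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    wide = series.pivot(index="block", columns="bin", values=column).sort_index()
    first = wide[1].to_numpy(dtype=float)
    last = wide[BINS_PER_BLOCK].to_numpy(dtype=float)
    online = last - first
    offline = first[1:] - last[:-1]
    return online, offline


def change_scores(flagged: pd.DataFrame, participant_id: str | None = None) -> ChangeScores:
    """Online and offline change vectors for one participant."""
    if participant_id is None:
        participant_id = (
            str(flagged["participant_id"].iloc[0])
            if "participant_id" in flagged
            else ""
        )
    scores = bin_scores(flagged)
    online_sl, offline_sl = _changes(scores, "learning_score")
    online_gs, offline_gs = _changes(scores, "median_rt")
    return ChangeScores(participant_id, online_sl, offline_sl, online_gs, offline_gs)


def change_scores_frame(all_scores: list[ChangeScores],
                        groups: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per participant with the four mean change scores."""
    rows = []
    for cs in all_scores:
        rows.append(
            {
                "participant_id": cs.participant_id,
                "group": (groups or {}).get(cs.participant_id, ""),
                "mean_online_sl": cs.mean_online_sl,
                "mean_offline_sl": cs.mean_offline_sl,
                "mean_online_gs": cs.mean_online_gs,
                "mean_offline_gs": cs.mean_offline_gs,
            }
        )
    return pd.DataFrame(rows)


def summarize_changes(frame: pd.DataFrame) -> pd.DataFrame:
    """Group-level means, SDs and one-sample t-tests vs 0 for each measure.

    ``frame`` is the output of :func:`change_scores_frame`. Returns a tidy
    table with one row per (group, measure).
    """
    measures = [
        "mean_online_sl",
        "mean_offline_sl",
        "mean_online_gs",
        "mean_offline_gs",
    ]
    rows = []
    for group, sub in frame.groupby("group"):
        for m in measures:
            values = sub[m].dropna().to_numpy()
            res = one_sample_t(values, 0.0) if len(values) >= 2 else None
            rows.append(
                {
                    "group": group,
                    "measure": m,
                    "n": len(values),
                    "mean": float(np.mean(values)) if len(values) else np.nan,
                    "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
                    "t": res.t if res else np.nan,
                    "df": res.df if res else np.nan,
                    "p": res.p if res else np.nan,
                }
            )
    return pd.DataFrame(rows)
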