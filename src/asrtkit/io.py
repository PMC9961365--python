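"""Tidy-CSV readers/writers, run configuration, and the end-to-end pipeline.

One long-format trial table is the single interchange format: one row per
trial with participant metadata repeated per row (columns listed in
``TRIAL_COLUMNS``). RTs are milliseconds, rests are seconds, indices are
1-based; practice blocks, when present, carry block <= 0 and are ignored by
every scoring stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import dynamics, pdp, preprocessing, scoring
from .inference import group_descriptives, mixed_anova_contract
from .preprocessing import QCCriteria
from .synthetic import (
    ParticipantRecord,
    SimulationConfig,
    cohort_frame,
    simulate_cohort,
    simulate_pdp_runs,
)
from .task_model import SequenceSpec, classify_triplets

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sequence",
    "block",
    "trial",
    "position",
    "response",
    "rt_ms",
    "correct",
    "rest_before_s",
    "block_start_latency_ms",
]

REQUIRED_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "position",
    "rt_ms",
    "correct",
]


class SchemaError(ValueError):
    """Raised when an input file does not match the trial-table schema."""


def write_trials(records: list[ParticipantRecord] | pd.DataFrame, path) -> None:
    """Write the tidy trial CSV (RFC-4180, LF line endings)."""
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    df = df.reindex(columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_trials(path) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Read a tidy trial CSV into typed participant records.

    Malformed rows (position/response outside 1-4, non-positive indices,
    missing RT with a recorded response) are collected into the returned
    rejects frame with a ``reject_reason`` column — never silently dropped.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("empty trial file: %s", path)
        return [], df
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad_pos = ~pos.isin([1, 2, 3, 4])
    reasons[bad_pos] = "position outside 1..4"
    if "response" in df.columns:
        resp = pd.to_numeric(df["response"], errors="coerce")
        bad_resp = resp.notna() & ~resp.isin([1, 2, 3, 4])
        reasons[bad_resp & (reasons == "")] = "response outside 1..4"
    trial_idx = pd.to_numeric(df["trial"], errors="coerce")
    bad_trial = trial_idx.isna() | (trial_idx < 1)
    reasons[bad_trial & (reasons == "")] = "invalid trial index"

    rejects = df[reasons != ""].copy()
    rejects["reject_reason"] = reasons[reasons != ""]
    good = df[reasons == ""].copy()

    records = []
    for pid, sub in good.groupby("participant_id", sort=True):
        sub = sub.sort_values(["block", "trial"])
        seq_text = str(sub["sequence"].iloc[0]) if "sequence" in sub else "1234"
        spec = SequenceSpec.from_string(seq_text)
        n_blocks = int(sub["block"].max())
        rests = (
            sub.groupby("block")["rest_before_s"].first().reindex(
                range(2, n_blocks + 1)
            ).tolist()
            if "rest_before_s" in sub
            else []
        )
        latencies = (
            sub.groupby("block")["block_start_latency_ms"].first().reindex(
                range(1, n_blocks + 1)
            ).tolist()
            if "block_start_latency_ms" in sub
            else []
        )
        trials = sub[
            [c for c in ["block", "trial", "position", "role", "response",
                         "rt_ms", "correct"] if c in sub.columns]
        ].reset_index(drop=True)
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                group=str(sub["group"].iloc[0]) if "group" in sub else "",
                age=float(sub["age"].iloc[0]) if "age" in sub else float("nan"),
                sequence=spec,
                trials=trials,
                rest_durations=rests,
                block_start_latencies=latencies,
            )
        )
    return records, rejects


class RunConfig(BaseModel):
    """Full pipeline configuration (schema-validated before any stage runs)."""

    seed: int = 1
    out_dir: str = "results"
    qc: QCCriteria = Field(default_factory=QCCriteria)
    unit_size: int = 5
    bins_per_block: int = 5
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    run_pdp: bool = True
    pdp_bias_inclusion: float = 0.25
    pdp_bias_exclusion: float = 0.10
    pdp_n_runs: int = 4

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def _annotate(record: ParticipantRecord, criteria: QCCriteria) -> pd.DataFrame:
    learning = record.trials[record.trials["block"] >= 1]
    classified = classify_triplets(learning, record.sequence)
    return preprocessing.flag_trials(classified, criteria)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> qc -> score -> dynamics -> pdp -> analyze.

    Writes ``trials.csv``, ``units.csv``, ``changes.csv``, the exclusion
    report, ``results.json`` and a run manifest into ``config.out_dir``.
    Identical config + seed reproduce every output byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation.model_copy(update={"seed": config.seed})

    stage = "simulate"
    try:
        records = simulate_cohort(sim)
        write_trials(records, out / "trials.csv")

        stage = "qc"
        flagged = {}
        status = {}
        groups = {r.participant_id: r.group for r in records}
        for r in records:
            flagged[r.participant_id] = _annotate(r, config.qc)
            status[r.participant_id] = preprocessing.participant_filter(r, config.qc)
        all_flagged = pd.concat(flagged.values(), ignore_index=True)
        report = preprocessing.build_exclusion_report(all_flagged, status)
        (out / "exclusion_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
        (out / "exclusion_report.txt").write_text(report.to_text() + "\n")
        kept = {pid for pid, (ok, _) in status.items() if ok}

        stage = "score"
        unit_scores = {
            pid: scoring.score_participant(
                flagged[pid], sim.n_blocks, config.unit_size, pid
            )
            for pid in sorted(kept)
        }
        units = scoring.unit_scores_frame(unit_scores, groups)
        units.to_csv(out / "units.csv", index=False, lineterminator="\n")

        stage = "dynamics"
        all_changes = [
            dynamics.change_scores(flagged[pid], pid) for pid in sorted(kept)
        ]
        changes = dynamics.change_scores_frame(all_changes, groups)
        changes.to_csv(out / "changes.csv", index=False, lineterminator="\n")
        change_summary = dynamics.summarize_changes(changes)

        stage = "pdp"
        pdp_results = []
        if config.run_pdp:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x9D9])
            )
            for r in records:
                if r.participant_id not in kept:
                    continue
                for condition, bias in (
                    ("inclusion", config.pdp_bias_inclusion),
                    ("exclusion", config.pdp_bias_exclusion),
                ):
                    runs = simulate_pdp_runs(
                        r.sequence, condition, config.pdp_n_runs, bias,
                        seed=rng, participant_id=r.participant_id,
                    )
                    runs = pdp.filter_runs(runs)
                    pdp_results.append(
                        {
                            "participant_id": r.participant_id,
                            "group": r.group,
                            "condition": condition,
                            "high_prob_ratio": pdp.high_prob_ratio(runs, r.sequence),
                        }
                    )
        pdp_frame = pd.DataFrame(pdp_results)

        stage = "analyze"
        results: dict = {"change_summary": change_summary.to_dict(orient="records")}
        final_unit = units[units["unit"] == units["unit"].max()]
        desc = group_descriptives(
            {g: sub["learning_score"].to_numpy()
             for g, sub in final_unit.groupby("group")}
        )
        results["final_unit_learning"] = desc.to_dict(orient="records")
        if units["group"].nunique() > 1 and units["participant_id"].nunique() > 3:
            aov = mixed_anova_contract(
                units.dropna(subset=["learning_score"]),
                dv="learning_score", within="unit", between="group",
            )
            results["learning_anova"] = aov.to_dict(orient="records")
        if len(pdp_frame):
            pdp_tests = []
            for (group, condition), sub in pdp_frame.groupby(["group", "condition"]):
                ratios = sub["high_prob_ratio"].dropna()
                if len(ratios) >= 2:
                    res = pdp.chance_test(ratios)
                    pdp_tests.append(
                        {"group": group, "condition": condition, **res.to_dict()}
                    )
            results["pdp_vs_chance"] = pdp_tests
            pdp_frame.to_csv(out / "pdp_ratios.csv", index=False, lineterminator="\n")
        (out / "results.json").write_text(
            json.dumps(results, indent=2, default=float) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_json = config.model_dump_json()
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": _package_version(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results


def _package_version() -> str:
    try:
        return _pkg_version("asrtkit")
    except Exception:
        return "unknown"
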