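"""Quality-control rules and the exclusion report."""

import numpy as np
import pandas as pd
import pytest

from asrtkit.preprocessing import (
    PipelineOrderError,
    QCCriteria,
    build_exclusion_report,
    flag_trials,
    participant_filter,
)
from asrtkit.synthetic import SimulationConfig, simulate_participant
from asrtkit.task_model import classify_triplets

from conftest import flagged_participant, noiseless_config


def make_trials(rows):
    """Build a classified one-block fixture from (position-triplet info) rows.

    Each row: (triplet, is_trill, is_repetition, correct, rt_ms).
    """
    n = len(rows)
    return pd.DataFrame(
        {
            "block": 1,
            "trial": range(1, n + 1),
            "position": 1,
            "triplet": [r[0] for r in rows],
            "is_trill": [r[1] for r in rows],
            "is_repetition": [r[2] for r in rows],
            "correct": [r[3] for r in rows],
            "rt_ms": [r[4] for r in rows],
        }
    )


class TestFlagTrials:
    def test_rt_cutoff_is_strict(self):
        trials = make_trials(
            [("unclassifiable", False, False, 1, 400),
             ("unclassifiable", False, False, 1, 400),
             ("low", False, False, 1, 1000.0),
             ("low", False, False, 1, 1000.1)]
        )
        out = flag_trials(trials)
        assert not out["excl_long_rt"].iloc[2]  # exactly 1000 ms is kept
        assert out["excl_long_rt"].iloc[3]

    def test_overlapping_reasons_counted_once_in_total(self):
        trials = make_trials(
            [("unclassifiable", False, False, 1, 400),
             ("unclassifiable", False, False, 1, 400),
             ("low", True, False, 0, 400)]  # both incorrect and a trill
        )
        out = flag_trials(trials)
        row = out.iloc[2]
        assert row["excl_incorrect"] and row["excl_trill"]
        report = build_exclusion_report(out)
        assert report.reason_counts["incorrect"] == 1
        assert report.reason_counts["trill"] == 1
        assert report.n_excluded == 3  # 2 unclassifiable + 1 overlapping
        assert report.n_excluded < sum(report.reason_counts.values()) + 1

    def test_hand_counted_fixture(self):
        """2 trills + 1 repetition + 1 incorrect + 1 long RT, no overlaps."""
        rows = [("unclassifiable", False, False, 1, 400)] * 2
        rows += [("low", True, False, 1, 400)] * 2          # 2 trills
        rows += [("low", False, True, 1, 400)]              # 1 repetition
        rows += [("high", False, False, 0, 400)]            # 1 incorrect
        rows += [("high", False, False, 1, 1200)]           # 1 long RT
        rows += [("high", False, False, 1, 400)] * 3        # clean
        out = flag_trials(make_trials(rows))
        beyond_unclassifiable = out["excluded"] & ~out["excl_unclassifiable"]
        assert int(beyond_unclassifiable.sum()) == 5
        assert int(out["excluded"].sum()) == 7

    def test_requires_classified_triplets(self):
        with pytest.raises(PipelineOrderError):
            flag_trials(pd.DataFrame({"rt_ms": [1.0], "correct": [1]}))

    def test_flags_idempotent_and_nonmutating(self):
        flagged = flagged_participant(SimulationConfig(seed=5, n_blocks=5))
        again = flag_trials(flagged)
        pd.testing.assert_series_equal(flagged["excluded"], again["excluded"])
        pd.testing.assert_series_equal(flagged["rt_ms"], again["rt_ms"])

    def test_order_independent(self):
        flagged = flagged_participant(SimulationConfig(seed=5, n_blocks=5))
        shuffled = flagged.sample(frac=1.0, random_state=0)
        reflagged = flag_trials(shuffled).sort_index()
        pd.testing.assert_series_equal(
            flagged["excluded"], reflagged["excluded"]
        )

    def test_incorrect_rate_matches_configured_error_rate(self):
        flagged = flagged_participant(SimulationConfig(seed=3, error_rate=0.09))
        assert flagged["excl_incorrect"].mean() == pytest.approx(0.09, abs=0.02)


def participant_frame(accuracy=1.0, latency=300.0, n_late=0, age=25.0,
                      first_rt=400.0, n_blocks=25):
    """Minimal per-participant frame for the participant-level rules."""
    n = n_blocks * 8
    rng = np.random.default_rng(0)
    correct = (rng.random(n) < accuracy).astype(int)
    df = pd.DataFrame(
        {
            "participant_id": "p",
            "age": age,
            "block": np.repeat(np.arange(1, n_blocks + 1), 8),
            "trial": np.tile(np.arange(1, 9), n_blocks),
            "position": 1,
            "rt_ms": 500.0,
            "correct": correct,
        }
    )
    df.loc[df["trial"] == 1, "rt_ms"] = first_rt
    lat = np.full(n_blocks, latency)
    lat[:n_late] = 1501.0
    df["block_start_latency_ms"] = np.repeat(lat, 8)
    return df


class TestParticipantFilter:
    def test_low_accuracy_excluded(self):
        kept, reasons = participant_filter(participant_frame(accuracy=0.70))
        assert not kept and "accuracy" in reasons

    def test_accuracy_threshold_strict(self):
        df = participant_frame()
        df["correct"] = 1
        df.loc[df.index[: int(0.2 * len(df))], "correct"] = 0  # exactly 80%
        kept, reasons = participant_filter(df)
        assert kept  # 80.0% is not below 80%

    def test_late_block_starts_in_five_blocks_excluded(self):
        kept, reasons = participant_filter(participant_frame(n_late=5))
        assert not kept and "late_block_start" in reasons
        kept4, _ = participant_filter(participant_frame(n_late=4))
        assert kept4

    def test_slow_first_trials_excluded(self):
        kept, reasons = participant_filter(participant_frame(first_rt=1100.0))
        assert not kept and "slow_first_trials" in reasons

    def test_age_rule(self):
        kept, reasons = participant_filter(participant_frame(age=36.0))
        assert not kept and "age" in reasons
        assert participant_filter(participant_frame(age=35.0))[0]

    def test_clean_record_kept(self):
        kept, reasons = participant_filter(participant_frame())
        assert kept and reasons == []

    def test_missing_latencies_skip_rule_with_warning(self, caplog):
        df = participant_frame().drop(columns=["block_start_latency_ms"])
        with caplog.at_level("WARNING"):
            kept, _ = participant_filter(df)
        assert kept
        assert any("latency" in m for m in caplog.messages)

    def test_works_on_participant_record(self):
        cfg = SimulationConfig(seed=2, n_blocks=5)
        rec = simulate_participant(cfg, "fixed_15", "p1")
        kept, reasons = participant_filter(rec)
        assert kept and reasons == []


class TestExclusionReport:
    def test_schema_complete_and_deterministic(self):
        flagged = flagged_participant(SimulationConfig(seed=8, n_blocks=5))
        a = build_exclusion_report(flagged)
        b = build_exclusion_report(flagged)
        assert a.to_dict() == b.to_dict()
        for reason in ("incorrect", "trill", "repetition", "long_rt", "unclassifiable"):
            assert reason in a.reason_counts

    def test_known_percentage(self):
        rows = [("unclassifiable", False, False, 1, 400)] * 2
        rows += [("low", False, False, 1, 400)] * 45
        rows += [("low", True, False, 1, 400)] * 3  # 3 trills
        out = flag_trials(make_trials(rows))
        report = build_exclusion_report(out)
        assert report.n_trials == 50
        assert report.n_excluded == 5
        assert report.percent_excluded == pytest.approx(10.0)

    def test_participant_status_included(self):
        flagged = flagged_participant(SimulationConfig(seed=8, n_blocks=5))
        report = build_exclusion_report(
            flagged, {"p1": (True, []), "p2": (False, ["accuracy"])}
        )
        assert report.participants["p2"]["status"] == "excluded"
        assert "p2" in report.to_text()
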