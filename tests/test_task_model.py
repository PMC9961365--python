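"""Sequence space, stream generation and the triplet classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest

from asrtkit.task_model import (
    InvalidConfigurationError,
    MalformedDataError,
    SequenceSpec,
    classify_triplets,
    enumerate_sequences,
    expected_high_fraction,
    generate_stream,
)


def brute_force_triplet(a: int, b: int, c: int, spec: SequenceSpec) -> tuple[str, bool, bool]:
    """Independent triplet oracle by direct definition."""
    category = "high" if c == spec.successor_map[a] else "low"
    is_trill = a == c and b != c
    is_rep = a == b == c
    return category, is_trill, is_rep


class TestSequenceSpace:
    def test_exactly_24_distinct_valid_specs(self):
        specs = enumerate_sequences()
        assert len(specs) == 24
        assert len({s.pattern for s in specs}) == 24
        assert {s.pattern for s in specs} == set(itertools.permutations((1, 2, 3, 4)))

    def test_successor_map_is_a_single_4_cycle(self):
        for spec in enumerate_sequences():
            pos = 1
            seen = []
            for _ in range(4):
                pos = spec.successor_map[pos]
                seen.append(pos)
            assert pos == 1  # composed 4 times -> identity
            assert sorted(seen) == [1, 2, 3, 4]

    def test_invalid_pattern_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            SequenceSpec((1, 1, 2, 3))

    def test_string_round_trip(self):
        spec = SequenceSpec.from_string("2,4,3,1")
        assert spec.pattern == (2, 4, 3, 1)
        assert SequenceSpec.from_string(spec.to_string()) == spec


class TestStreamGeneration:
    def test_block_and_template_structure(self, spec):
        stream = generate_stream(spec, 25, 80, rng_seed=3)
        assert len(stream) == 2000
        assert stream["block"].nunique() == 25
        per_block = stream.groupby("block").size()
        assert (per_block == 80).all()
        # roles strictly alternate starting with a pattern trial
        roles = stream["role"].to_numpy()
        assert all(roles[i] == ("pattern" if i % 2 == 0 else "random")
                   for i in range(160))
        # pattern trials follow the successor map exactly
        pat = stream.loc[stream["role"] == "pattern", "position"].to_numpy()
        succ = spec.successor_map
        assert all(succ[a] == b for a, b in zip(pat[:-1], pat[1:]))

    def test_single_template_matches_pattern(self, spec):
        stream = generate_stream(spec, 1, 8, rng_seed=0)
        pattern_slots = stream.loc[stream["role"] == "pattern", "position"]
        assert tuple(pattern_slots) == spec.pattern

    def test_same_seed_identical_stream(self, spec):
        a = generate_stream(spec, 5, 80, rng_seed=11)
        b = generate_stream(spec, 5, 80, rng_seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_trials_per_block_must_be_multiple_of_8(self, spec):
        with pytest.raises(InvalidConfigurationError):
            generate_stream(spec, 2, 79)

    def test_random_trials_uniform_over_positions(self, spec):
        stream = generate_stream(spec, 1250, 80, rng_seed=5)  # 1e5 trials
        rnd = stream.loc[stream["role"] == "random", "position"]
        freqs = rnd.value_counts(normalize=True)
        assert np.allclose(freqs.reindex([1, 2, 3, 4]), 0.25, atol=0.01)


class TestTripletClassifier:
    def test_agrees_with_brute_force_oracle_all_triples_all_specs(self):
        """Exhaustive: all 64 position triples under each of the 24 specs."""
        for spec in enumerate_sequences():
            for a, b, c in itertools.product((1, 2, 3, 4), repeat=3):
                frame = pd.DataFrame(
                    {"block": [1, 1, 1], "trial": [1, 2, 3], "position": [a, b, c]}
                )
                row = classify_triplets(frame, spec).iloc[2]
                category, trill, rep = brute_force_triplet(a, b, c, spec)
                assert row["triplet"] == category
                assert row["is_trill"] == trill
                assert row["is_repetition"] == rep

    def test_printed_examples(self, spec):
        frame = pd.DataFrame(
            {"block": [1] * 6, "trial": range(1, 7),
             "position": [1, 2, 1, 1, 1, 4]}
        )
        out = classify_triplets(frame, spec)
        assert list(out["triplet"][:2]) == ["unclassifiable"] * 2
        assert bool(out["is_trill"].iloc[2])     # 1-2-1
        assert bool(out["is_repetition"].iloc[4])  # 1-1-1 at trials 3,4,5
        assert not bool(out["is_trill"].iloc[4])

    def test_triplets_never_span_blocks(self, spec):
        stream = generate_stream(spec, 3, 16, rng_seed=1)
        out = classify_triplets(stream, spec)
        firsts = out[out["trial"] <= 2]
        assert (firsts["triplet"] == "unclassifiable").all()
        rest = out[out["trial"] > 2]
        assert (rest["triplet"] != "unclassifiable").all()

    def test_position_out_of_range_rejected(self, spec):
        frame = pd.DataFrame({"block": [1], "trial": [1], "position": [5]})
        with pytest.raises(MalformedDataError):
            classify_triplets(frame, spec)

    def test_pattern_trials_always_high(self, spec):
        stream = generate_stream(spec, 25, 80, rng_seed=9)
        out = classify_triplets(stream, spec)
        pattern = out[(out["role"] == "pattern") & (out["triplet"] != "unclassifiable")]
        assert (pattern["triplet"] == "high").all()

    def test_high_low_fractions_converge(self, spec):
        stream = generate_stream(spec, 1250, 80, rng_seed=2)
        out = classify_triplets(stream, spec)
        cl = out[out["triplet"] != "unclassifiable"]
        assert (cl["triplet"] == "high").mean() == pytest.approx(0.625, abs=0.01)
        assert (cl["triplet"] == "low").mean() == pytest.approx(0.375, abs=0.01)

    @pytest.mark.parametrize("perm", list(itertools.permutations((1, 2, 3, 4)))[:8])
    def test_relabelling_equivariance(self, spec, perm):
        """Relabelling positions and the spec alike leaves labels unchanged."""
        relabel = dict(zip((1, 2, 3, 4), perm))
        stream = generate_stream(spec, 2, 80, rng_seed=4)
        base = classify_triplets(stream, spec)
        mapped = stream.assign(position=stream["position"].map(relabel))
        mapped_spec = SequenceSpec(tuple(relabel[p] for p in spec.pattern))
        out = classify_triplets(mapped, mapped_spec)
        assert list(out["triplet"]) == list(base["triplet"])
        assert list(out["is_trill"]) == list(base["is_trill"])
        assert list(out["is_repetition"]) == list(base["is_repetition"])


class TestExpectedHighFraction:
    def test_analytic_values(self):
        assert expected_high_fraction("asrt") == 0.5 + 0.5 * 0.25 == 0.625
        assert expected_high_fraction("pure_random") == 0.25
        assert 1 - expected_high_fraction("asrt") == 0.375

    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            expected_high_fraction("bogus")
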