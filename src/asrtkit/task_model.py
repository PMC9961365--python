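"""ASRT sequence structure and triplet taxonomy.

The alternating serial reaction time (ASRT) task presents stimuli in one of
four horizontal positions (numbered 1-4, left to right). Every other trial
follows a fixed four-element pattern cycle; the trials in between are drawn
uniformly at random, e.g. the eight-element template ``2 - r - 4 - r - 3 -
r - 1 - r``. Because pattern trials are predictable from the trial two steps
back, some runs of three consecutive stimuli ("triplets") occur with high
probability (62.5% of trials) and the rest with low probability (37.5%).
This module defines the sequence space, stimulus-stream generation, and the
triplet classifier every downstream score consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIONS = (1, 2, 3, 4)

#: Fraction of trials forming a high-probability triplet in the ASRT design:
#: pattern trials (half of all trials) are always high; random trials are
#: high when they happen to hit the pattern successor (1 in 4).
ASRT_HIGH_FRACTION = 0.5 + 0.5 * 0.25

#: Chance level for the generation (PDP) task: after any two presses the
#: third press completes a high-probability triplet with probability 1/4.
PURE_RANDOM_HIGH_FRACTION = 0.25


class InvalidConfigurationError(ValueError):
    """Raised when a task/stream configuration violates the design."""


class MalformedDataError(ValueError):
    """Raised when trial data contain impossible values (e.g. position 5)."""


@dataclass(frozen=True)
class SequenceSpec:
    """One of the 24 ASRT pattern sequences.

    Parameters
    ----------
    pattern
        The four pattern positions in presentation order, a permutation of
        1-4. The pattern is cyclic: after the fourth element it restarts.
    """

    pattern: tuple[int, int, int, int]
    successor_map: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if tuple(sorted(self.pattern)) != POSITIONS:
            raise InvalidConfigurationError(
                f"pattern must be a permutation of 1-4, got {self.pattern}"
            )
        succ = {
            self.pattern[i]: self.pattern[(i + 1) % 4] for i in range(4)
        }
        object.__setattr__(self, "successor_map", succ)

    @classmethod
    def from_string(cls, text: str) -> "SequenceSpec":
        """Parse ``"2431"`` or ``"2,4,3,1"`` into a spec."""
        digits = [int(c) for c in text.replace(",", "").replace(" ", "")]
        return cls(tuple(digits))  # type: ignore[arg-type]

    def to_string(self) -> str:
        return "".join(str(p) for p in self.pattern)


def enumerate_sequences() -> list[SequenceSpec]:
    """All 24 possible ASRT sequences (the 4! pattern permutations)."""
    return [SequenceSpec(p) for p in itertools.permutations(POSITIONS)]


def generate_stream(
    spec: SequenceSpec,
    n_blocks: int,
    trials_per_block: int = 80,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate an ASRT stimulus stream.

    Each block starts with a pattern trial; pattern and random trials then
    strictly alternate, so a block of 80 trials is the eight-element
    template repeated 10 times. The pattern phase is continuous across
    blocks.

    Parameters
    ----------
    spec
        The participant's sequence.
    n_blocks
        Number of learning blocks.
    trials_per_block
        Must be a positive multiple of 8 (the template length).
    rng_seed
        Integer seed or a ``numpy.random.Generator``. The same seed always
        yields the identical stream.

    Returns
    -------
    DataFrame with columns ``block`` (1-based), ``trial`` (1-based within
    block), ``position`` (1-4) and ``role`` (``pattern``/``random``).
    """
    if trials_per_block <= 0 or trials_per_block % 8 != 0:
        raise InvalidConfigurationError(
            f"trials_per_block must be a positive multiple of 8, got {trials_per_block}"
        )
    if n_blocks < 1:
        raise InvalidConfigurationError("n_blocks must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = n_blocks * trials_per_block
    # pattern trials at odd global indices (0, 2, 4, ...): cycle the pattern
    n_pattern = n // 2
    pattern_positions = np.resize(np.array(spec.pattern, dtype=np.int8), n_pattern)
    positions = np.empty(n, dtype=np.int8)
    positions[0::2] = pattern_positions
    positions[1::2] = rng.integers(1, 5, size=n - n_pattern, dtype=np.int8)
    roles = np.empty(n, dtype=object)
    roles[0::2] = "pattern"
    roles[1::2] = "random"
    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, n_blocks + 1), trials_per_block),
            "trial": np.tile(np.arange(1, trials_per_block + 1), n_blocks),
            "position": positions,
            "role": roles,
        }
    )


def classify_triplets(stream: pd.DataFrame, spec: SequenceSpec) -> pd.DataFrame:
    """Label every trial as the third element of a triplet.

    A trial is *high*-probability when its position equals the pattern
    successor of the position two trials earlier, *low* otherwise. Triplets
    never span block boundaries, so the first two trials of each block are
    *unclassifiable*. Trills (x-y-x) and repetitions (x-x-x) are flagged on
    the third element; the two flags are mutually exclusive, and neither can
    be high-probability (the pattern successor map has no fixed point).

    Returns a copy of ``stream`` with added columns ``triplet``
    (``high``/``low``/``unclassifiable``), ``is_trill``, ``is_repetition``.
    """
    pos = stream["position"].to_numpy()
    if pos.size and (pos.min() < 1 or pos.max() > 4):
        raise MalformedDataError("positions must lie in 1..4")
    block = stream["block"].to_numpy()
    succ = np.array([0] + [spec.successor_map[p] for p in POSITIONS], dtype=np.int8)

    p2 = np.roll(pos, 2)  # position two trials back
    p1 = np.roll(pos, 1)
    same_block = np.zeros(len(pos), dtype=bool)
    if len(pos) > 2:
        same_block[2:] = block[2:] == block[:-2]

    high = same_block & (pos == succ[p2])
    trill = same_block & (p2 == pos) & (p1 != pos)
    repetition = same_block & (p2 == pos) & (p1 == pos)

    out = stream.copy()
    triplet = np.full(len(pos), "low", dtype=object)
    triplet[high] = "high"
    triplet[~same_block] = "unclassifiable"
    out["triplet"] = triplet
    out["is_trill"] = trill
    out["is_repetition"] = repetition
    return out


def classify_presses(presses: np.ndarray, spec: SequenceSpec) -> pd.DataFrame:
    """Triplet-classify a single run of key presses (PDP generation task).

    Same taxonomy as :func:`classify_triplets` with the run treated as one
    uninterrupted block: the first two presses are unclassifiable.
    """
    presses = np.asarray(presses)
    frame = pd.DataFrame(
        {
            "block": np.ones(len(presses), dtype=int),
            "trial": np.arange(1, len(presses) + 1),
            "position": presses,
        }
    )
    return classify_triplets(frame, spec)


def expected_high_fraction(mode: str) -> float:
    """Analytic high-probability triplet fraction.

    ``asrt``: pattern trials are always high, random trials are high with
    probability 1/4, so 0.5 + 0.5*0.25 = 0.625. ``pure_random``: uniform
    presses complete a high triplet with probability 1/4 = 0.25.
    """
    if mode == "asrt":
        return ASRT_HIGH_FRACTION
    if mode == "pure_random":
        return PURE_RANDOM_HIGH_FRACTION
    raise InvalidConfigurationError(f"unknown mode {mode!r}")
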