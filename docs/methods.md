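# Methods

## Task model

The ASRT stimulus stream alternates pattern and random trials. A
`SequenceSpec` is one of the 24 permutations of positions 1–4; its
`successor_map` is the cyclic pattern transition (a single 4-cycle, so it
has no fixed points — a fact the triplet taxonomy relies on: a trill
(x-y-x) or repetition (x-x-x) can never be a high-probability triplet).
Each block starts with a pattern trial at within-block index 1 and the
8-element template repeats exactly ten times per 80-trial block, so the
pattern phase is automatically continuous across blocks. Whether the
delivered task starts blocks on a pattern or a random element does not
affect triplet probabilities; the convention here (pattern first) matches
the printed template and is a documented choice, not an inference from
data.

Triplet classification: trial *n* (third element) is high-probability iff
`position(n) == successor_map(position(n−2))`. Triplets are computed within
blocks only, so the first two trials of every block are unclassifiable.
Trill/repetition flags attach to the third element. An exhaustive oracle
(all 64 position triples × all 24 sequences) and a relabelling-equivariance
property pin the classifier down completely in the tests.

## Synthetic cohort

The simulator is a generative stand-in for a behavioral cohort, built to
exercise every pipeline stage, not to model cognition. Per trial:

```
RT = baseline_rt − skill(b) + fatigue(b, k) − δ(b, k)·1[high] + ε,   ε ~ N(0, noise_sd)
```

- `skill(b) = skill_gain·(1 − exp(−skill_growth_rate·b))` — saturating
  block-wise speedup (defaults 60 ms total, rate 0.12/block).
- `δ(b, k) = learning_effect_max·(1 − exp(−learning_growth_rate·b)) +
  learning_online_ramp·(k−1)/4` — the high/low gap, growing across blocks
  (defaults 25 ms asymptote, rate 0.15/block; `learning_growth_rate = inf`
  gives a constant δ, the noiseless-plant configuration used for exactness
  tests). The optional within-block ramp (default 0) adds
  `learning_online_ramp` ms from bin 1 to bin 5; because bin 1 of the next
  block restarts at the block-level curve, the ramp also produces the
  across-rest reset (offline forgetting) without a separate parameter.
- `fatigue(b, k)` accumulates `fatigue_slope` ms per 16-trial bin (default
  3 ms); each rest clears up to `offline_recovery` ms of accumulated
  fatigue (default 20 ms — clears fully), so within-block slowing recovers
  across rests.
- RTs are floored at 150 ms (no RT distribution is prescribed for the
  task; additive Gaussian noise is the simplest model adequate for
  median-based scoring, and the floor prevents non-physiological values).
- With probability `long_rt_rate` (default 0.0024) a trial's RT is
  resampled uniformly in (1000, 1500] ms, exercising the >1000 ms rule.
- Correctness is Bernoulli(1 − `error_rate`), default 9% errors; incorrect
  trials keep the same RT model (no error-specific shift).
- Rests: fixed groups get constant 15 s or 30 s; the self-paced group draws
  lognormal(μ = ln 10.58, σ = 0.954) seconds. The two parameters are solved
  from a 10.58 s median and 16.67 s mean; the SD of a two-parameter
  lognormal is then determined (~25 s) and is an approximation, not a fit.
- Block-start latencies are N(500, 150) ms; a `late_starter_rate` flag
  produces N(1800, 200) ms latecomers to exercise the latency rule.

Determinism: every participant's stream derives from
`SeedSequence([cohort_seed, crc32(participant_id)])`, so records are
reproducible individually and in any cohort order.

What the simulator does **not** emulate: RT autocorrelation and sequential
effects beyond the triplet structure, error-RT coupling, post-error
slowing, between-participant variance components (no published values to
target), explicit-awareness dynamics in generation beyond a single
pattern-following `bias` probability. Passing tests therefore certify the
*pipeline arithmetic* under realistic marginal statistics, not cognitive
fidelity.

## Quality control

Trial flags are computed independently from the raw trial (idempotent,
order-independent): incorrect, trill, repetition, RT strictly > 1000 ms,
unclassifiable. Overlaps are reported per reason and counted once in the
total. The accuracy rule (< 80%) is evaluated over learning-block trials
only (practice blocks, marked `block <= 0`, never enter scoring); whether
practice trials counted in the original operationalization is unstated, and
learning-blocks-only is consistent with the analysis scope. Exclusions that
depend on other tasks (n-back accuracy, restarts, prior participation) are
caller-supplied metadata — they cannot be computed from ASRT trial data and
pretending otherwise would hide an unverifiable step. Missing responses are
treated as incorrect with missing RT and never enter RT statistics.

## Scoring

Unit scores pool all eligible trials of five consecutive blocks; medians
are pooled (not averaged per block), and an even-count median is the
midpoint of the central pair. The standardization denominator is the mean
RT of the same unit's eligible trials — a per-unit normalization; per-
participant or grand-mean denominators are plausible alternatives and can
be computed from the same table, but the per-unit version keeps the score
self-contained. Units missing either triplet category yield NaN, never 0.

## Online/offline decomposition

Bins are fixed on the design grid (positions 1–16, …, 65–80); exclusions
thin a bin rather than shift boundaries. Bin learning scores use medians
(low − high) to mirror the unit convention. Sign conventions: positive
`online_sl` = within-block gain, negative `offline_sl` = forgetting across
the rest, positive `online_gs` = within-block slowing, negative
`offline_gs` = RT recovery across the rest. The decomposition satisfies a
telescoping identity — `sum(online) + sum(offline) = last bin − first bin`
— exactly when no bin is missing; missing bins propagate as NaN and means
are taken over available entries. On the noiseless plant the recovered
online/offline values equal the programmed ramp and reset exactly; with
noise the estimator is unbiased (checked by Monte-Carlo at n = 150) with a
per-participant SD of roughly 13 ms under default noise.

## Generation task (PDP)

Triplets are computed within runs only (each run restarts the two-press
warm-up), so a 24-press run has 22 classifiable presses. Runs with > 50%
(strictly) trills/repetitions among classifiable presses are removed;
trill/repetition presses in kept runs remain in the denominator — removing
them would move the chance level away from 25%, which anchors the test.
The per-participant percentage is compared to 25 with a one-sample t-test.

## Inference

`one_sample_t` is computed from the definition `t = (x̄ − μ₀)·√n / s` with
a two-sided p from the t distribution (cross-checked against an
independent routine in the tests); a zero-variance sample returns t = 0 at
the null mean and an infinite-statistic marker otherwise. The mixed-design
ANOVA is delegated to an established repeated-measures routine behind a
fixed schema (F, df pair, p, partial η²); its sums-of-squares convention is
the delegated routine's and is recorded as such rather than guessed.
Greenhouse–Geisser-corrected p-values are used when the routine provides a
sphericity decision; otherwise uncorrected df are reported with a logged
caveat. Bayes-factor columns exist in the schema but are never computed
here (off-the-shelf machinery, intentionally out of scope). Bonferroni
correction multiplies p by the number of comparisons, capped at 1.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen for tight Monte-Carlo error at
interactive runtimes: 100,000 trials for triplet-frequency convergence
(binomial SE ≈ 0.15 pp), ≥ 10,000 classifiable presses for the 25% chance
level (SE ≈ 0.4 pp), 90 participants for δ-recovery (95% CI half-width
≈ 2 ms), 60 participants for the online/offline sign pattern (> 99% power
for a 10 ms ramp given the ~13 ms score SD), and 25 replicates for the
ANOVA detection check. The analysis scripts run a 60-participant,
three-group cohort. All randomness flows from explicit integer seeds.

## Known limitations

- The simulator's group differences are limited to rest schedules; it does
  not implement group-specific learning or consolidation effects, so
  between-group hypotheses can only be exercised, not validated, against it.
- `ExclusionReport` reports pairwise overlap only implicitly (total vs
  sum); it does not enumerate every reason combination.
- The mixed-ANOVA contract supports one within and one between factor —
  the shape used here — not general factorial designs.
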