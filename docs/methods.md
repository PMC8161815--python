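# Methods

## Scope and data model

The package validates a device-scored hypnogram against a PSG-scored one.
A hypnogram is a sequence of stage labels on a uniform epoch grid
(default 30 s). Epochs are 0-based; epoch *i* spans the half-open interval
[start + i·d, start + (i+1)·d). Three alphabets are supported: the five
AASM stages (Wake, N1, N2, N3, REM) for PSG, and the two wearable
conventions Wake–Light–Deep–REM ("type I") and Wake–Light–Deep
("type II"). No raw signal processing is performed: the inputs are already
staged sequences.

## Synchronization

Both recordings carry clock times; the device sequence is placed on the
PSG epoch grid by rounding the start-time offset to the nearest whole
epoch and truncating both sequences to the overlapping interval. Bare
hh:mm:ss times (no date) are resolved across midnight by shifting the
offset into ±12 h. Hypnograms with different epoch durations are first
resampled to the coarser duration — label repetition when refining,
within-block majority vote (earlier label wins ties) when coarsening —
preserving stage dwell rather than inventing stages. Partial final epochs
of annotation tracks are truncated. Synchronization is idempotent, and the
aligned length never exceeds the shorter input.

## Stage categorization

PSG stages are collapsed to the device alphabet before any pairwise
metric: N1, N2 → Light; N3 → Deep; REM → REM (type I) or Deep (type II);
Wake → Wake. The wake/sleep partition is preserved exactly, which makes
the wake-sleep features below invariant under categorization.

## Sleep features

All computed within one hypnogram, durations in minutes:

| feature | definition | default |
|---|---|---|
| SO | first non-Wake epoch (index, clock time, and minutes from recording start) | — |
| SPT | (last sleep epoch − SO + 1) · d | — |
| TST | sleep epochs within [SO, LSP], split into TLST/TDST/TRST | — |
| SE | 100 · TST / SPT | — |
| WASO | SPT − TST + WAS | WAS = 0 |
| PLS/PDS/PRS | 100 · TLST/TDST/TRST over TST | PRS absent for 3-stage alphabets |

SPT counts the last sleep epoch's full duration (a closed span in epochs);
a pure clock difference LSP − SO would silently drop one epoch and make
epoch counts irreproducible. WAS — wake between the last sleep epoch and
lights-on — is zero for hypnogram-only input because no lights-on event is
recorded; supplying a lights-on time counts the wake epochs that fit
wholly before it. An all-wake night raises a distinct no-sleep error
rather than returning sentinel feature values. Sleep onset is compared
across nights on the minutes-from-recording-start scale, since raw clock
times are not subtractable across midnight.

## Localized mismatch index

Stages are encoded Wake = 1, Light = 2, Deep = 4; transition deltas are
first differences, the transition set A collects the epochs where either
scorer changed stage, and LMI_i is the product of the two deltas. The
encoding makes every transition's delta magnitude unique (1, 2, 3), so the
6×6 product table is symmetric with diagonal {1, 4, 9}.

Classification is pair-based, one rule for both alphabets:

* **correct** iff the two deltas are equal (and nonzero); *wake* subclass
  when the transition involves Wake (|Δ| ∈ {1, 3}, plus 7 in 4-stage
  mode), *sleep* subclass otherwise.
* **incorrect** otherwise. The wake/sleep split reduces each delta to its
  *wake direction* — sign(Δ) when the transition involves Wake, else 0.
  Equal wake directions mean the scorers agree on the wake-crossing
  component and the error is in sleep depth (incorrect_sleep: products 3
  and −4 in 3-stage mode, and one-sided sleep-only transitions); unequal
  directions mean a missed, spurious or reversed wake transition
  (incorrect_wake: all remaining products and one-sided wake-involving
  transitions).

In 3-stage mode this reproduces the canonical product grouping
(correct wake {1, 9}, correct sleep {4}, incorrect sleep {3, −4},
incorrect wake {2, 6, −1, −2, −3, −6, −9}) exactly — verified exhaustively
over all 7×7 delta pairs in the tests. One-sided epochs (product 0) are
members of A by the ∨-definition and are always disagreements. Because
the rule uses the delta *pair*, not the product, it extends unchanged to
4-stage mode, where the default REM code of 8 keeps all delta magnitudes
distinct ({1, 2, 3, 4, 6, 7}); the REM code is configurable and cannot
change any class.

Rates are percentages over |A|, not over all epochs: the four class
percentages sum to 100 and overall correct + overall incorrect = 100,
which is the only denominator under which per-class transition summaries
are comparable across nights with different transition counts. Strict
per-epoch matching is intentional — a transition detected one epoch late
scores as two one-sided disagreements, with no lag credit.

## Interrater gate and statistics

Fleiss' κ over the rater panel (statsmodels backend) gates the PSG ground
truth at κ ≥ 0.8 (boundary passes; κ < 0.8 flags concurrent revision).
Total agreement returns κ = 1 even when only one category appears, where
the raw formula degenerates to 0/0.

Per-night features are compared device-vs-PSG across nights. Normality of
the paired differences is decided by Shapiro–Wilk at α = 0.05 — the test
choice is thereby data-driven per feature: paired *t* when normal,
Wilcoxon signed-rank otherwise. The effect size is the signed paired
Cohen's d = mean(diff)/sd(diff) with diff = device − PSG. All-zero
differences short-circuit to a degenerate no-difference result (p = 1).
No multiple-testing correction is applied by default. Confusion metrics
use device × PSG count matrices; a stage never scored by the PSG has
undefined (flagged, not zero) sensitivity. Cohort reports rank devices per
feature by descending p-value (larger p = closer to PSG), ties broken by
smaller |effect|.

## Synthetic nights

The simulator exists so every metric has a closed-loop test against known
ground truth. PSG nights are first-order Markov chains over the five AASM
stages, 960 epochs of 30 s (~8 h) by default, starting awake. The default
transition matrix encodes mean bout lengths of roughly 2 min (Wake),
1.5 min (N1), 12.5 min (N2), 11 min (N3) and 9 min (REM), yielding a stage
mix roughly matching adult norms (light ~50%, deep ~20%, REM ~25% of the
sleep period, wake ~5%). These are plausible defaults chosen once, not a
fitted population model.

The device channel corrupts the *categorized* PSG truth with, in order:
a transition-lag distribution (each stage boundary slips by a sampled
number of epochs, kept monotonic by clipping), a per-stage mislabel matrix,
and a per-epoch dropout probability (dropped epochs carry the previous
reported label forward; the first epoch is always reported). The returned
ground-truth record flags every modified epoch, so expected accuracy and
transition rates are exact bookkeeping rather than estimates.

What the simulator does *not* emulate: ultradian cycle structure beyond
first-order dwell, stage-dependent device bias profiles of real trackers,
sensor-loss bursts, or scorer drift across the night. Passing tests
therefore demonstrate correctness of the metrics under known error
structure, not the field performance of any real device.

Per-night seeds derive from the master seed via `numpy.random.SeedSequence`
spawning; identical scenarios produce byte-identical datasets.

## Numerical and test-scale choices

Stochastic matrices are validated to row sums of 1 within 1e-9. Feature
identities are asserted to 1e-9 or exactly where arithmetic is exact in
binary floating point (epoch counts × 0.5 min). Property suites use 1000
simulated nights of 120 epochs for the feature invariants (the invariants
are length-independent), 30 nights of 960 epochs per mislabel rate for
parameter recovery (3 binomial σ bands), 10,000 epochs for the
chance-level kappa check, and 1000 replicates at n = 30 for the type-I
calibration of the paired suite.

## Known limitations

* The 4-stage LMI table is generated by the pair-based rule; no external
  reference table for 4-stage products is bundled.
* Lag and mislabel channels compose sequentially; simultaneous lag +
  mislabel at the same boundary can cancel in principle, which the
  bookkeeping handles by comparing reported to true labels directly.
* EDF+ ingestion maps annotation tracks only; it does not validate the
  underlying signal montage.
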