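# hypnoval

Validation of wearable sleep-tracker hypnograms against polysomnography
(PSG) ground truth.

Consumer wearables stage sleep from wrist motion and cardiorespiratory
signals, but their hypnograms are scored by vendor algorithms on coarser
stage sets than the AASM stages a sleep physician assigns from PSG.
Classical validation summaries (overall accuracy, Bland–Altman limits,
Cohen's kappa) say *how much* two hypnograms disagree but not *where*:
they ignore the chronology of sleep-stage transitions, which is precisely
what screening for insomnia, narcolepsy or fragmented sleep depends on.
`hypnoval` implements an epoch-by-epoch validation pipeline for sleep
researchers and device evaluators:

1. **Synchronization** of PSG and device hypnograms onto a common 30-s
   epoch grid by clock time.
2. **AASM-based stage categorization**: PSG stages Wake/N1/N2/N3/REM are
   collapsed to the device's alphabet — N1, N2 → Light; N3 → Deep; REM
   stays REM for "type I" devices (Wake–Light–Deep–REM) or folds into Deep
   for "type II" devices (Wake–Light–Deep).
3. **Interrater gating**: when several raters scored the PSG, Fleiss'
   κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) must reach 0.8 or the hypnogram is flagged for
   concurrent revision.
4. **Feature comparison**: TST, SPT, SE, WASO, SO and the stage-distribution
   percentages (PLS/PDS/PRS), compared across nights by paired *t* or
   Wilcoxon signed-rank tests with a signed paired Cohen's *d*.
5. **Localized mismatch index (LMI)** — the core statistic. Stages are
   encoded Wake = 1, Light = 2, Deep = 4 (REM = 8 in 4-stage mode); with
   Y_P and Y_W the encoded PSG and wearable sequences, the deltas are
   ΔY_i = Y_{i+1} − Y_i, the transition set is
   A = {i : ΔY_P,i ≠ 0 ∨ ΔY_W,i ≠ 0}, and

       LMI_i = ΔY_W,i × ΔY_P,i        for i ∈ A.

   The six legal 3-stage transitions W–L, W–D, L–D, L–W, D–L, D–W carry
   deltas 1, 3, 2, −1, −2, −3, so the LMI table is symmetric with diagonal
   {1, 4, 9} marking correctly detected transitions. Each transition epoch
   is classed as correct wake {1, 9}, correct sleep {4}, incorrect sleep
   {3, −4}, or incorrect wake (everything else, including one-sided
   transitions where only one scorer changed stage), and the class
   percentages over A summarize how faithfully the device tracks the
   night's transition structure.
6. **Confusion metrics**: per-stage sensitivity/specificity and overall
   epoch accuracy.

A first-order Markov simulator generates paired PSG/device nights with a
controllable error channel (per-stage mislabeling, transition lag, epoch
dropout) and exact ground-truth bookkeeping, so every metric has a
closed-loop test without recorded data.

## Worked example

`examples/01_compare_night.py` simulates an 8-h night, corrupts the device
channel with 20% uniform epoch mislabels, and compares:

```
night of 960 epochs (480 min)
     psg: TST  464.5 min  SPT  479.0 min  SE  97.0%  WASO  14.5 min  PLS  57.1%  PDS  42.9%
  device: TST  428.5 min  SPT  479.0 min  SE  89.5%  WASO  50.5 min  PLS  55.2%  PDS  44.8%
epoch accuracy: 79.90% (planted: 80%)
transitions: 342 epochs in the transition set; correct 7.3% (wake 3.2%, sleep 4.1%)
```

The epoch accuracy recovers the planted 80% agreement, while the
correct-transition rate collapses to 7.3%: random mislabels create many
spurious transitions, and the LMI localizes exactly that disagreement —
the behaviour that overall accuracy alone cannot see. The other examples
print the full LMI product table with its class grouping
(`02_lmi_table.py`), a two-device cohort comparison with paired tests and
ranking (`03_cohort_tests.py`), and Fleiss-kappa gating of a rater panel
(`04_interrater_gate.py`).

## Command line

```sh
hypnoval simulate --nights 30 --seed 7 --out dataset/
hypnoval compare --psg dataset/psg_000.csv --device dataset/device_000.csv \
         --device-type II --out report/
hypnoval cohort --manifest dataset/manifest.csv --out cohort_report/
```

Reports are JSON plus CSV tables; every report embeds the run
configuration and package version.

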