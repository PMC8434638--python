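# Methods

This note documents the models, conventions and design choices behind
`keydyn`, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design being modeled

A within-subject semi-experiment: each participant writes four opinions
(best/worst teacher, best/worst subject) at a standardized workstation while
an anonymizing logger records one row per key event — millisecond timestamp,
key *class*, opaque slot id, DOWN/UP, and a capture-time capital flag for
letters.  Letter and digit identities are never stored; the slot id exists
only so DOWN/UP can be paired.  Before the first opinion and after each one
the participant files a SAM self-report of pleasure, arousal and dominance
on a 9-point pictorial scale, **inverted**: 1 is the high end, 9 the low
end.  A complete 49-participant study yields 196 opinion segments and 245
self-reports.

Opinion boundaries come from a JSON sidecar (the analogue of wall-clock
times noted between opinions); slicing is half-open `[start_i, start_{i+1})`
and events before the first boundary (intake questionnaire typing) are
excluded from analysis.

## Segmentation

* **Pairing.**  Each DOWN is matched to the earliest subsequent UP with the
  same slot id.  Rollover is normal typing.  An UP with no pending DOWN is
  dropped with a warning; a DOWN that never releases gets its hold imputed
  as the median matched hold of the same batch (warned, counted).  Nothing
  in pairing is a fatal error: real capture logs contain these artifacts.
* **Idle splitting.**  Sequences split where the flight gap — previous
  release to next press — **strictly exceeds** the threshold (default
  3000 ms; a gap exactly at the threshold does not split, matching the
  "exceeded" reading).  Negative gaps (rollover) never split.  Whether the
  original instrumentation split on release→press or press→press gaps is
  not derivable from its description; release→press is the standard
  keystroke-dynamics convention and the default, with `gap_mode =
  "press_press"` available for sensitivity analysis.

## The 51 features

Graphs are consecutive press pairs/triples **within** a typing sequence,
pooled across all sequences of a segment before statistics are taken
(per-sequence statistics averaged afterwards would weight short sequences
heavily; pooling is the simpler convention and is what the brute-force test
oracle verifies).  Conventions that required a decision:

* **Standard deviation** is population (÷n): deterministic for a single
  graph (0, not undefined).
* **NumEvents** counts every raw event with timestamp in the closed window
  from the graph's first press to its last release — 4/6 for clean
  digraphs/trigraphs, more under rollover interleaving.
* **Shift digraphs** (first press is left/right shift) feed the dedicated
  `L_*`/`R_*` features *and* remain in the general digraph pool; nothing in
  the feature definitions says they are removed from it.  `*_first_shift_up`
  is the fraction of shift digraphs whose shift release strictly precedes
  the second key's release, reported on [0, 1].
* **CAPS** is capital letters ÷ letters.  The feature table's short gloss
  ("caps lock frequency") conflicts with the prose definition
  (capital-letter ratio); the prose is the more specific statement and is
  the default, `caps_mode = "capslock_count"` restores the other reading.
* **SPEED** divides presses by elapsed segment time (first to last event).
  `speed_mode = "active"` divides by the summed span of typing sequences
  instead, for users who want pause-free speed.
* **Missing, not zero.**  A feature whose pool is empty (no trigraphs, no
  shifts, no letters) is NaN.  Zeros would be fabricated timings; imputation
  happens at modeling time, with training-fold column means.

The whole-session **baseline** vector pools graphs over all four opinion
slices (sequences never span the gaps between opinions); its SPEED
denominator is the summed per-slice elapsed time, so inter-opinion breaks do
not dilute it.  The *relative* dataset subtracts the user's baseline from
each of their four segment vectors; missing entries stay missing.

## Statistics

* **Paired t-test**: t = d̄/(s_d/√n), sample s_d, df = n−1, two-sided.
  Pairs are within user and topic: (best teacher, worst teacher) and (best
  subject, worst subject) — 98 pairs in a complete study, 49 per topic
  subset.  Zero-variance differences are an error, not p = 1.
* **Benjamini–Hochberg**: step-up, r* = max{r : p₍ᵣ₎ ≤ qr/n}, rejecting the
  r* smallest p-values.  Ties break by original index, making selection
  deterministic.  Verified against exhaustive cutoff search and
  statsmodels' `fdr_bh` on random vectors.
* **Mann–Whitney / Wilcoxon**: scipy implementations behind a stable
  result type; U is reported for the first sample; exact p for small
  tie-free samples (verified against complete enumeration in the tests),
  tie-corrected normal approximation otherwise.  Wilcoxon drops zero
  differences (the `wilcox` policy) and errors when all differences are
  zero.
* **Mutual information**: the k-nearest-neighbour estimator
  (`mutual_info_classif`, default k = 3, seeded — the estimator jitters to
  break ties), clipped at 0.  MI values in nats.

The packaged reference tables (`keydyn/data/*.csv`) are the published
per-feature p-values and MI scores of the motivating study.  They are
*inputs* — realistic 51-dimensional test batteries for the multiple-testing
and thresholding code paths — not regeneration targets: reproducing them
would require that study's raw keystroke recordings, which this package
deliberately does not depend on.

## Classification protocol

Stratified 10-fold outer CV.  Inside each training fold, in order:
column-mean imputation → optional z-scoring → variance screen (default
threshold 1e-10) → correlation screen (drop the later column of any pair
with |r| > 0.95, scanning in canonical feature order for determinism) →
grid search by inner 3-fold CV (RBF-SVM: C ∈ {0.1, 1, 10, 100}, γ ∈
{scale, 0.01, 0.1, 1}).  Fold-held-out predictions are pooled into a single
confusion matrix; the valence task reports macro averages, the
pleasure/arousal tasks support-weighted averages (their classes are
imbalanced by construction of the merge rules).  Nested tuning is the
default because it is leakage-safe; `nested=False` tunes once on the full
data for replication of non-nested protocols.  Class imbalance is reported,
not resampled.  Random forest, naive Bayes and k-NN are available behind
the same interface; the SVM is the default model.

PAD merge rules on the inverted scale: L1 maps >5 → Low, <5 → High and
removes 5s; L2 maps ≥5 → Low; L3 maps ≤5 → High.

## Synthetic study generator

The generator emulates the capture setting, not language.  Per user, a
profile is drawn from population hyper-distributions: log-normal hold times
(median ≈ 95 ms across users, within-user σ 0.25–0.40) and flights (median
≈ 170 ms, σ 0.40–0.60) — the common empirical shape for keystroke
latencies — a pause process (per-keystroke probability 1–4% of an idle gap
of 3000 ms + Exp(2000 ms), guaranteeing threshold-exceeding splits),
rollover probability 3–10% (negative flights of 5–50 ms), spacebar
probability ≈ 0.16, backspace 2–8%, small delete/arrow rates, capital rate
2–6% with a left/right shift preference.  Capitals are preceded by a shift
press that is released before or after the letter's release with equal
probability, exercising the `first_shift_up` features both ways.

Condition effects enter through `EffectSpec`: flights multiply by
`speed_factor` in negative opinions (default 1.15 — the direction, slower
typing under negative affect, follows the literature; the magnitude is a
plausibility choice), the spacebar probability shifts by `space_delta`
(default −0.02), and self-reports draw from a discretized, clipped normal
per dimension and condition.  The default report means (pleasure 3.24/4.14,
arousal 4.97/4.36, dominance 5.67/5.63 for positive/negative, SD 2.0)
reproduce the sample means observed in the motivating study's reports, on
the inverted scale; time-point-0 reports use a neutral pre-task state.
`EffectSpec.null()` removes every condition difference.

What the generator does **not** model: linguistic structure (no words, no
language-dependent digraph frequencies), fatigue or drift within a session,
inter-key dependence of hold times, and any dominance effect.  Passing
recovery tests therefore shows the pipeline detects effects of the modeled
kind at realistic sizes — it does not certify performance on human data,
where effects are entangled with content and far smaller (the motivating
study's valence F1 was ≈ 0.62).

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run at the full study width (49 users) but modest
segment lengths (60–150 keystrokes per opinion; the defaults use 250), a
size at which every assertion has been observed to be stable while keeping
the suite fast.  The null-effect chance-level check averages macro F1 over
a 60-seed prefix; the strong-effect (speed_factor 1.3) and
relative-vs-absolute checks use 20 seeds.  The acceptance script averages
classification F1 over 5 seeds derived from `--seed`.

## Known limitations

* Feature extraction is defined for millisecond-integer capture; other
  resolutions must be converted at ingest.
* The paired-test module assumes each user contributes exactly one segment
  per opinion kind; incomplete sessions simply contribute fewer pairs.
* The MI estimator is biased for strongly discrete features (many exact
  ties); reference MI values contain exact zeros consistent with a clipped
  k-NN estimator, and no attempt is made to match a specific estimator
  configuration beyond that family.
* With 4 samples per user, per-user personalized thresholds or classifiers
  are out of reach by design.
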