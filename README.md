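# keydyn

Keystroke-dynamics analysis of positive vs. negative opinion writing.

`keydyn` is a tested, reusable implementation of a behavioural-biometrics
pipeline for a within-subject study design in which each participant types
four short opinions — best/worst teacher and best/worst subject — while an
anonymizing key logger records key-down/key-up events, and files a 9-point
SAM (Self-Assessment Manikin) pleasure/arousal/dominance self-report before
the first opinion and after each one.  The scientific question: do keystroke
timing and frequency patterns differ between positive and negative opinions,
and can valence (or self-reported pleasure/arousal level) be predicted from
them?

It is aimed at affective-computing and behavioural-biometrics researchers
who want the full analysis chain — raw event processing through statistics
and classification — as an importable, seedable library, exercised end to
end on a synthetic study generator so that no human data are needed to run,
test or extend it.

## What the pipeline computes

1. **Segmentation.** DOWN/UP events are paired into key presses (rollover —
   pressing key *i*+1 before releasing key *i* — is preserved, not an
   error).  Presses are split into typing sequences wherever the flight gap
   (release *i* → press *i*+1) exceeds the 3 s idle threshold.
2. **51 features per opinion segment.**  For digraphs (consecutive press
   pairs) and trigraphs (triples), the timing parameters 1D2D (press→press),
   nDur (hold), nKeyLat (flight, possibly negative), Dur (graph span) and
   NumEvents are pooled across sequences; their mean `[0]` and population
   standard deviation `[1]` are features.  Shift-initiated digraphs get
   dedicated timing features plus the fraction released before the second
   key.  Frequency features count spacebar, backspace, delete, arrows and
   shifts over total presses, plus the capital-letter ratio; SPEED is
   keystrokes per second.
3. **Baseline normalization.**  Each user's whole-session vector is a
   baseline; the *relative* dataset holds the four segment vectors minus
   that baseline, removing stable individual style.
4. **Feature evaluation.**  Per feature, a dependent-samples t-test
   t = d̄ / (s_d/√n) on within-user positive–negative pairs (df = n−1,
   two-sided), with Benjamini–Hochberg control of the false-discovery rate:
   reject the r* smallest p-values where r* = max{r : p₍ᵣ₎ ≤ qr/n}.
   Mutual information I(feature; class) is estimated with the k-NN
   estimator (k = 3).  Ordinal self-report labels are compared with
   Mann–Whitney (independent) and Wilcoxon signed-rank (paired) tests.
5. **Classification.**  Valence (positive/negative) and dichotomized
   High/Low pleasure or arousal (merge rules L1/L2/L3 around the scale
   midpoint 5, on the inverted 1 = high scale) are predicted by an
   RBF-SVM (or random forest / naive Bayes / k-NN) in stratified 10-fold
   cross-validation with per-training-fold imputation, optional scaling,
   variance/correlation feature screening and inner grid search; held-out
   predictions are pooled into one confusion matrix.
6. **Synthetic studies.**  `generate_study` simulates 49 participants × 4
   opinions with log-normal hold/flight times, pauses, rollover, special
   keys, shift-preceded capitals and condition-correlated self-reports; an
   `EffectSpec` injects known ground-truth condition effects (flight-time
   slowdown, spacebar shift) so recovery can be verified.

## Worked example

```python
from keydyn import (EffectSpec, assign_valence_labels, build_dataset,
                    cross_validated_classify, generate_study, make_relative)

effect = EffectSpec(speed_factor=1.3)      # negative opinions typed 1.3x slower
sessions = generate_study(n_users=49, effect=effect, seed=5, n_keystrokes_mean=150)
dataset, baselines = build_dataset(sessions)    # 196 segments x 51 features
labels = assign_valence_labels(dataset)         # 98 POSITIVE / 98 NEGATIVE

for variant, data in (("absolute", dataset),
                      ("relative", make_relative(dataset, baselines))):
    report = cross_validated_classify(data.X, labels, seed=5)
    print(variant, round(report.macro_f1, 3))
```

prints

```
absolute 0.637
relative 0.98
```

The injected slowdown is small next to between-user style differences
(absolute variant, F1 0.64) but large next to each user's own baseline
(relative variant, F1 0.98).  With `EffectSpec.null()` both variants sit at
chance (macro F1 ≈ 0.5).  The `examples/` directory has one short script per
capability: simulation, feature extraction, statistical screening,
classification, and PAD label handling.  A thin CLI mirrors the pipeline:
`keydyn simulate|featurize|stats|classify|run`.

The package also ships the published per-feature evaluation tables of the
motivating 49-participant study (`load_reference_pvalues`,
`load_reference_mutual_information`) as inputs for multiple-testing
demonstrations: at q = 0.05 the BH rule keeps exactly one of the 51
features — the spacebar frequency, p = 0.0007 — out of twelve raw p < 0.05.

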