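# emostage

Subject-independent emotion recognition from multichannel physiological
signals by a three-stage decision method.

## The problem

Physiological signals — EEG, skin conductance (GSR), blood volume pulse
(BVP), respiration, EMG, EOG, skin temperature — track emotional state,
but different people produce very different signal patterns for the
*same* emotion. A classifier trained on a pool of subjects therefore
degrades badly on a person it has never seen. `emostage` implements a
staged remedy for the four-quadrant problem (valence–arousal plane,
quadrants EQ1–EQ4, self-ratings on 1–9 with ">5 = high"):

1. **Stage 1 — subject grouping.** Training subjects are clustered into
   m groups by k-means over Fisher-selected physiological features; a
   test trial is assigned to a group by summed k-NN probabilities over
   its 29 four-second windows.
2. **Stage 2 — emotion pools.** Within the group, a C4.5 decision tree
   assigns the trial to one of two emotion pools (high vs low arousal
   {EQ1,EQ4}/{EQ2,EQ3}, or high vs low valence {EQ1,EQ2}/{EQ3,EQ4})
   using a path-probability rule that sums the class distributions of
   every tree node the window passes through.
3. **Stage 3 — emotion decision.** A random forest classifies each
   window inside the pool; the trial takes the majority emotion.

Each stage ranks the 742 windowed features (see below) by the Fisher
Criterion Score F = (m₁−m₂)²/(σ₁²+σ₂²) and sweeps the subset size on a
per-stage validation set. Evaluation is leave-one-subject-out (LOSO):
every fold retrains everything without the held-out subject.

The package is aimed at affective-computing researchers who want a
fully reproducible, inspectable implementation of the staged decision
procedure — including its feature set, validation-set construction and
comparison baselines — plus a synthetic multi-subject generator so the
whole pipeline can be exercised and unit-tested without access to any
restricted recording database.

## Features

Each 4 s window (2 s hop) of a 40-channel trial yields 742 named
features: per-EEG-channel statistics, band powers (theta 4–7, alpha
8–15, beta 16–31, gamma 32–45 Hz), power ratios and Hjorth parameters;
right-minus-left band-power asymmetry of 14 symmetric electrode pairs;
spectral entropy, Shannon entropy and C0 complexity; EOG/EMG/temperature
statistics; heart-rate and HRV measures from detected pulse peaks
(including pNN50 and the triangular index); respiration morphology and
breath-interval/amplitude series; and skin-conductance dynamics
(rise/decay times, difference statistics). `emostage.REGISTRY` carries
the canonical names and block layout.

## Worked example

```
python examples/03_three_stage_loso.py
```

simulates 6 subjects x 8 trials (20 s each, so 9 windows per trial)
with planted group, arousal and valence effects, runs the full
three-stage LOSO evaluation and prints:

```
method: three_stage[HA_LA]
four-emotion accuracy: 0.875 (48 trials, chance = 0.25)
per-emotion accuracy: {'EQ1': 0.818, 'EQ2': 0.909, 'EQ3': 0.923, 'EQ4': 0.846}
confusion matrix (rows = true emotion):
     EQ1  EQ2  EQ3  EQ4
EQ1    9    2    0    0
EQ2    1   10    0    0
EQ3    0    0   12    1
EQ4    0    0    2   11
stage diagnostics: {'pool_accuracy': 0.875, 'm_step1_mode': 2, 'group_ari_mean': 0.402, 'group_accuracy': 0.938}
```

Reading the numbers: 42 of 48 held-out trials received the correct
quadrant (chance would be 12); the intermediate high/low-arousal pool
decision was right 87.5% of the time; the first stage settled on m = 2
subject groups in most folds and sent 93.8% of test trials to the group
their subject's planted peers belong to. The other examples show
feature extraction (`01`), Fisher ranking of arousal markers (`02`) and
the comparison against direct, one-vs-rest and one-vs-one baselines
(`04`).

A thin CLI wraps the same calls: `emostage simulate --out dir/` writes
a synthetic study as TSV signals + metadata, and `emostage evaluate
--data dir/metadata.tsv --out results/` (or without `--data` to
simulate on the fly) runs the LOSO evaluation and writes
`report.json` + `confusion.tsv`.

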