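# Methods

`emostage` implements a three-stage decision procedure for recognizing
four emotions — the quadrants EQ1–EQ4 of the valence–arousal plane —
from multichannel physiological recordings in the *subject-independent*
setting, where the classifier must work for people it never saw during
training. The design premise is that inter-individual differences in
physiological baselines are large relative to emotion effects, so a
single pooled classifier underperforms; the remedy is to first place a
test trial within a *group* of physiologically similar training
subjects and only then classify its emotion inside that group.

## Signal model and features

A trial is a one-minute, 40-channel recording (32 EEG electrodes in the
10-20 montage plus GSR, skin temperature, BVP, respiration, two EMG and
two EOG leads) with valence and arousal self-ratings on a 1–9 scale.
Ratings map to quadrants with a strict ">5 = high" rule; ties at 5 are
low. Signals are cut into 4-second windows advanced by 2 seconds, so a
60 s trial yields 29 windows, and each window is summarized by 742
named features in nine blocks (EEG time/frequency and Hjorth
parameters; hemispheric band-power asymmetries of 14 symmetric
electrode pairs; spectral/Shannon entropy and C0 complexity; EOG, EMG
and temperature statistics; heart-rate and HRV features from detected
pulse peaks; respiration morphology; skin-conductance dynamics).
Feature columns are min–max normalized to [0,1] on training data only;
a `pooled` option restores whole-dataset normalization for strict
procedure reproduction at the cost of mild leakage.

Numerical conventions (degenerate inputs included):

* All moments are population moments (divide by *n*); kurtosis is the
  excess form. Constant windows have skewness = kurtosis = 0 and all
  Hjorth parameters 0.
* Band power is the mean of the mean-removed FFT periodogram over bins
  whose center lies in the half-open band [lo, hi); an empty band has
  power 0, and power ratios with a zero denominator are 0. With 4 s
  windows the spectral resolution is 0.25 Hz, so sub-0.25 Hz bands
  (temperature, slow respiration bands) are usually empty — they are
  retained for fidelity to the feature table but carry no variance.
* Local-extremum counts (the MinRatio/MaxRatio features) use cyclic
  slope-sign alternation: zero slopes inherit the previous sign and the
  sign sequence is closed circularly. This makes the counts symmetric
  for periodic signals and zero for monotone ones.
* Hjorth mobility/complexity follow the variance-of-derivative
  definitions; C0 complexity is the share of spectral power outside the
  above-mean-power FFT components; Shannon entropy uses 16 equal-width
  amplitude bins over the window's own range.
* Pulse peaks are detected on the 0.5–8 Hz band-passed BVP with a
  0.35 s minimum inter-peak distance; breaths by upward zero crossings
  of the mean-removed respiration trace with one peak per cycle.
  pNN50 divides the >50 ms count by the number of adjacent interval
  pairs; the HRV triangular index uses the conventional 1/128 s
  histogram bin.
* Windows with fewer than two beats (or breaths, for the derived
  respiration series) flag those features missing; missing cells are
  imputed with the training-set column median before normalization.

## The three stages

**Fisher ranking.** Every stage selects features with the Fisher
Criterion Score F = (m1−m2)² / (s1²+s2²) (population standard
deviations). A zero denominator scores +inf when the means differ
(a perfect separator ranks first) and 0 otherwise. For more than two
classes (subject identification) the score is the mean of one-vs-rest
scores. Ties break toward the lower feature index.

**Stage 1 — subject grouping.** Per emotion, training windows are
labeled with subject ids and ranked; the top-fe1 sets of the four lists
are intersected (fe1 swept over a grid) and the intersection that best
classifies a validation set by subject wins (ties toward the smaller
fe1 and smaller k-NN k). k-means (10 restarts, seeded) clusters the
training windows on that subset for m = 2..5; each subject joins the
cluster holding most of its windows; an m leaving any group under 3
subjects (2 in the scaled-down study conditions used by the tests) is
rejected as "extremely uneven", and if every m is rejected the
procedure falls back to m = 2. A final Fisher ranking against the group
labels fixes the stage-1 feature count fe_step1. At test time each of a
trial's windows gets a k-NN probability vector (neighbor count / k)
over groups; vectors are summed across the trial (the total equals the
window count) and the argmax group wins, ties to the lower id.

**Stage 2 — emotion pools.** The four quadrants are paired into two
pools, either by arousal (HA = {EQ1, EQ4} vs LA = {EQ2, EQ3}) or by
valence (HV = {EQ1, EQ2} vs LV = {EQ3, EQ4}). Within each group a
C4.5-style tree (binary midpoint splits chosen by information gain
ratio, minimum leaf 2, pessimistic pruning with confidence 0.25,
Laplace-smoothed class distributions stored at every node) is trained
on the Fisher-selected subset, with fe2 swept against the group's
validation trials. A window's pool probability is obtained by walking
its root-to-leaf path, summing the node distributions and normalizing;
per-trial sums again total the window count and the argmax pool wins.
The tree is hand-implemented because the path-probability rule needs
the internal node distributions, which off-the-shelf trees do not
expose; the Laplace smoothing is a declared deviation that keeps path
sums non-degenerate.

**Stage 3 — emotion decision.** Inside the assigned (group, pool) a
random forest (100 trees, sqrt feature subsampling, bootstrap, seeded)
classifies every window; the trial takes the emotion with the majority
of window votes (ties, impossible at 29 windows, go to the
lower-numbered quadrant).

## Evaluation protocol

Evaluation is leave-one-subject-out: all three stages are retrained per
fold on the remaining subjects. Within a fold's training subjects, the
stage-1 validation set holds one trial per subject (covering the four
emotions greedily; a subject's only trial of an emotion stays in
training); stages 2 and 3 move one random trial per (subject, emotion)
above a count threshold into validation — strictly more than 5 trials
for stage 2 and more than 4 for stage 3, each relaxing one step at a
time (to >3, >2, >1) for an emotion nobody qualifies for, so the
validation set always covers both classes when any subject has at least
two trials of each. With balanced synthetic labels (17 trials over 4
quadrants) the unrelaxed thresholds would select nothing, which is why
the ladder exists; a subject always keeps one trial of the emotion in
training. An audit asserts that no window of the held-out subject
reaches any training structure.

Baselines under the identical protocol: a direct four-class classifier
(1-NN, linear SVM with C = 200 and tol = 1e-3, C4.5 or random forest)
on one vector per trial (the mean of its window vectors; a
flag-switchable single-window variant exists); one-vs-rest (4 binary
classifiers) and one-vs-one (6) window-level 1-NN ensembles fused per
trial by majority voting (counting per-window binary decisions) or the
sum rule (summing class-probability supports). Reports carry the 4x4
confusion matrix, per-emotion and trial-weighted average accuracy, and
per-stage diagnostics. Rater agreement is the mean over stimuli of the
fraction of subject pairs assigning the same quadrant.

## Synthetic studies

The generator emulates the target study design — 32 subjects x 17
one-minute trials at 128 Hz, 40 channels — with planted, recoverable
structure. EEG channels are synthesized in the frequency domain (pink
broadband base plus theta/alpha/beta/gamma plateaus with random
phases); effects add in the log-power domain:

* **group signature** (`group_effect`, default 1.0): a broadband
  baseline shift of ±group_effect/2 separating two subject groups —
  the dominant axis of inter-individual variation;
* **subject signature** (`subject_sd`, default 0.35): per-subject
  band-by-region log-power offsets plus individual heart-rate,
  skin-conductance, respiration-rate and temperature baselines;
* **arousal** (`arousal_effect`, default 0.5): high-arousal trials gain
  beta/gamma power, +8·effect bpm of heart rate and a higher phasic
  skin-conductance event rate;
* **valence** (`valence_effect`, default 0.4): frontal alpha power
  shifts toward the right hemisphere for high valence (pairs
  Fp1/Fp2, AF3/AF4, F3/F4, F7/F8), and the reverse for low.

BVP is a unit sine at the planted instantaneous rate with smooth rate
jitter scaled by `noise_sd`; respiration a ~0.25 Hz sine; EMG/EOG
parameterized noise with blink bumps on vEOG. Each stimulus has an
intended quadrant; a subject "feels" it with probability
`rating_agreement` (default 0.86) and otherwise one of the other three
quadrants — signals and self-ratings both follow the felt emotion, so
labels stay self-consistent while the panel's mean pairwise quadrant
agreement lands near the ~75% regime reported for human affect panels.
The defaults encode the regime the method presumes: group and subject
variation dominate emotion effects. The generator does not model
artifacts, nonstationary drift within a trial, volume conduction or
realistic pulse/breath morphology, so passing tests demonstrate that
the *procedure* recovers planted structure, not that it would reach any
particular accuracy on real recordings.

## Benchmark conditions and problem sizes

The test-suite and acceptance benchmarks run scaled-down studies chosen
as the smallest designs whose behavior is stable:

* *study condition* — 6–8 subjects x 8–12 trials x 20 s (9 windows per
  trial) at the default effects; five independently seeded studies give
  a mean four-emotion LOSO accuracy well above the 0.70 benchmark
  (chance 0.25).
* *recovery condition* — 10 subjects x 8 trials x 20 s with
  well-separated groups (`group_effect` 2.0, `subject_sd` 0.2): stage-1
  clustering recovers the planted partition (ARI ≥ 0.9) and ≥95% of
  held-out trials return to their subject's group. With the default
  subject scatter, single high-baseline subjects can be isolated as
  their own cluster (the same behavior the original study reports for
  its two-subject second group), which is why recovery is benchmarked
  at clear separation.
* *null condition* — all effects zero: accuracy falls to the 25%
  chance band, confirming the pipeline does not manufacture signal.

Sweep grids in these benchmarks use a coarse subset (5, 20, 80, 300,
742) of the full 1..742 step-5 grid; both are configurable
(`Stage1Config`/`Stage2Config`/`Stage3Config`).

## Known limitations

* The analysis sampling rate is data-driven; the defaults assume
  128 Hz-class preprocessed recordings.
* The C4.5 variant simplifies the original (binary numeric splits only,
  no subset splits on categorical attributes, no average-gain
  pre-filter); the EMG "total spectral power" band and the C0
  complexity variant follow declared conventions rather than a
  published formula.
* EDF files are read (via mne) but written only as TSV.
* Per-fold sweep selection with small validation sets is noisy; the
  tie-toward-smaller rule makes it deterministic but can pick very
  small feature sets on small panels.
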