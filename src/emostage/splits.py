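"""Leave-one-subject-out folds and per-stage validation-set construction.

Stage 1 validation takes one trial per training subject, jointly
covering the four emotions where possible; a trial that is its subject's
only instance of an emotion stays in training. Stages 2 and 3 move one
random trial per (subject, emotion) whose count exceeds a threshold —
5 for stage 2 and 4 for stage 3 — into validation; if no subject
qualifies for an emotion the threshold is relaxed one step at a time
(never below 2 trials, so a subject always keeps one instance in
training). All draws are taken from the supplied generator, so a fixed
seed reproduces the splits exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import DomainError, EMOTIONS

TrialKey = tuple[str, str]


@dataclass(frozen=True)
class LosoFold:
    test_subject: str
    training_subjects: tuple[str, ...]


def loso_folds(subjects) -> list[LosoFold]:
    """One fold per subject; each fold's training set excludes that subject."""
    subjects = sorted(subjects)
    if len(subjects) < 2:
        raise DomainError("leave-one-subject-out needs >= 2 subjects")
    return [LosoFold(s, tuple(x for x in subjects if x != s))
            for s in subjects]


def stage1_validation_split(trials: pd.DataFrame,
                            rng: np.random.Generator) -> list[TrialKey]:
    """Pick one validation trial per subject, covering emotions greedily.

    ``trials`` has one row per trial with subject_id, trial_id, emotion.
    Returns the validation trial keys; everything else stays in training.
    """
    counts = trials.groupby(["subject_id", "emotion"]).size()
    coverage = {e: 0 for e in EMOTIONS}
    val: list[TrialKey] = []
    subjects = sorted(trials["subject_id"].unique())
    order = rng.permutation(len(subjects))
    for si in order:
        subj = subjects[si]
        sub = trials[trials["subject_id"] == subj]
        # eligible: the subject keeps at least one trial of that emotion
        eligible = sub[sub["emotion"].map(
            lambda e: counts.get((subj, e), 0) >= 2)]
        if eligible.empty:
            continue
        least = min(coverage[e] for e in eligible["emotion"].unique())
        pick_pool = eligible[eligible["emotion"].map(coverage) == least]
        row = pick_pool.iloc[rng.integers(len(pick_pool))]
        val.append((row["subject_id"], row["trial_id"]))
        coverage[row["emotion"]] += 1
    return val


def _threshold_ladder_split(trials: pd.DataFrame, rng: np.random.Generator,
                            emotions, start_threshold: int) -> list[TrialKey]:
    """Per emotion, move one random trial from each subject above the
    highest populated threshold of the descending ladder."""
    val: list[TrialKey] = []
    counts = trials.groupby(["subject_id", "emotion"]).size()
    for emotion in emotions:
        for thr in range(start_threshold, 0, -1):
            qualifying = sorted(
                subj for (subj, e), c in counts.items()
                if e == emotion and c > thr)
            if qualifying:
                for subj in qualifying:
                    sub = trials[(trials["subject_id"] == subj)
                                 & (trials["emotion"] == emotion)]
                    row = sub.iloc[rng.integers(len(sub))]
                    val.append((row["subject_id"], row["trial_id"]))
                break
    return val


def stage2_validation_split(trials: pd.DataFrame, rng: np.random.Generator,
                            emotions=EMOTIONS) -> list[TrialKey]:
    """One random trial per (subject, emotion) with more than 5 trials.

    If no subject exceeds 5 for an emotion the threshold relaxes
    stepwise so the validation set still covers every emotion present.
    """
    present = [e for e in emotions if (trials["emotion"] == e).any()]
    return _threshold_ladder_split(trials, rng, present, start_threshold=5)


def stage3_validation_split(trials: pd.DataFrame, rng: np.random.Generator,
                            emotions) -> list[TrialKey]:
    """One random trial per (subject, emotion) with more than 4 trials,
    relaxing to >3 (and below) per emotion when nobody qualifies."""
    present = [e for e in emotions if (trials["emotion"] == e).any()]
    return _threshold_ladder_split(trials, rng, present, start_threshold=4)
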