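"""Stage 3: final two-emotion decision inside an emotion pool.

A random forest (100 trees, sqrt feature subsampling, bootstrap
resampling, seeded) classifies every window of a trial; the trial takes
the emotion holding the majority of the window votes. With the canonical
29 windows per trial a two-way tie is impossible; at even window counts
ties go to the lower-numbered emotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .fcs import rank_features
from .features.extract import WindowDataset
from .recording import DomainError, EMOTIONS


@dataclass
class Stage3Config:
    fe3_grid: tuple[int, ...] = tuple(range(1, 743, 5))
    n_trees: int = 100


@dataclass
class EmotionClassifier:
    """Trained stage-3 state for one (group, pool) pair."""

    group_id: int
    pool_id: int
    emotions: tuple[str, ...]
    feature_indices: np.ndarray
    forest: RandomForestClassifier = field(repr=False)
    seed: int = 0
    fe3: int = 0
    validation_accuracy: float = 0.0

    def decide_trial(self, trial_X: np.ndarray) -> tuple[str, dict[str, int]]:
        """Majority vote of per-window forest decisions; tie -> lower emotion."""
        preds = self.forest.predict(
            np.asarray(trial_X)[:, self.feature_indices])
        counts = {e: int(np.sum(preds == e)) for e in self.emotions}
        winner = max(self.emotions, key=lambda e: (counts[e], -EMOTIONS.index(e)))
        return winner, counts


def _trial_accuracy(clf: EmotionClassifier, val: WindowDataset) -> float:
    correct, total = 0, 0
    for _s, _t, emotion, X in val.iter_trials():
        pred, _ = clf.decide_trial(X)
        correct += int(pred == emotion)
        total += 1
    return correct / total if total else 0.0


def train_emotion_classifier(train: WindowDataset, val: WindowDataset,
                             group_id: int, pool_id: int,
                             emotions: tuple[str, ...], seed: int,
                             config: Stage3Config = Stage3Config()) -> EmotionClassifier:
    """Fisher-rank against the two pool emotions, sweep fe3, train the forest."""
    y = train.meta["emotion"].to_numpy()
    present = np.unique(y)
    if not all(e in present for e in emotions):
        raise DomainError(
            f"group {group_id} pool {pool_id}: an emotion is absent from training")
    ranked = rank_features(train.X, y, label_context=f"emotions|{emotions}")
    best = None   # (acc, -fe3, clf)
    for fe3 in config.fe3_grid:
        idx = np.sort(ranked.top(fe3))
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, max_features="sqrt",
            bootstrap=True, random_state=seed)
        forest.fit(train.X[:, idx], y)
        clf = EmotionClassifier(group_id=group_id, pool_id=pool_id,
                                emotions=emotions, feature_indices=idx,
                                forest=forest, seed=seed, fe3=fe3)
        acc = _trial_accuracy(clf, val) if len(val) else 0.0
        clf.validation_accuracy = acc
        cand = (acc, -fe3)
        if best is None or cand > best[:2]:
            best = (acc, -fe3, clf)
    return best[2]
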