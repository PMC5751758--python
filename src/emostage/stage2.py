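"""Stage 2: classify a trial into one of two emotion pools.

Two pooling schemes are supported: HA/LA pools the high-arousal
quadrants {EQ1, EQ4} against {EQ2, EQ3}, HV/LV pools the high-valence
quadrants {EQ1, EQ2} against {EQ3, EQ4}. Within a subject group the
features are Fisher-ranked against the pool labels, the subset size fe2
is swept on a validation set, and a C4.5 tree is trained on the best
subset. A trial's windows each receive the tree's path-probability
2-vector; summed over windows the larger pool total wins (tie -> pool 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .c45 import C45Tree
from .fcs import rank_features
from .features.extract import WindowDataset
from .recording import DomainError

POOL_SCHEMES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "HA_LA": (("EQ1", "EQ4"), ("EQ2", "EQ3")),
    "HV_LV": (("EQ1", "EQ2"), ("EQ3", "EQ4")),
}


@dataclass(frozen=True)
class PoolScheme:
    """A partition of the four quadrants into two disjoint emotion pools."""

    name: str
    pool1: frozenset[str]
    pool2: frozenset[str]

    @classmethod
    def by_name(cls, name: str) -> "PoolScheme":
        if name not in POOL_SCHEMES:
            raise DomainError(f"unknown pool scheme {name!r}")
        p1, p2 = POOL_SCHEMES[name]
        return cls(name, frozenset(p1), frozenset(p2))

    def pool_of(self, emotion: str) -> int:
        """1 or 2; the pool holding this emotion."""
        if emotion in self.pool1:
            return 1
        if emotion in self.pool2:
            return 2
        raise DomainError(f"unknown emotion {emotion!r}")

    def emotions(self, pool: int) -> tuple[str, ...]:
        members = self.pool1 if pool == 1 else self.pool2
        return tuple(sorted(members))


@dataclass
class Stage2Config:
    fe2_grid: tuple[int, ...] = tuple(range(1, 743, 5))
    min_leaf: int = 2
    confidence: float = 0.25


@dataclass
class PoolClassifier:
    """Trained stage-2 state for one subject group."""

    group_id: int
    scheme: PoolScheme
    feature_indices: np.ndarray
    tree: C45Tree = field(repr=False)
    fe2: int = 0
    validation_accuracy: float = 0.0

    def sample_probability(self, samples: np.ndarray) -> np.ndarray:
        """Path-probability 2-vector (pool 1, pool 2) per sample row."""
        return self.tree.predict_proba(
            np.asarray(samples)[:, self.feature_indices])

    def assign_trial(self, trial_X: np.ndarray) -> tuple[int, np.ndarray]:
        """Summed per-window pool probabilities; argmax pool, tie -> pool 1."""
        sums = self.sample_probability(trial_X).sum(axis=0)
        return int(self.tree.classes_[int(np.argmax(sums))]), sums


def pool_labels(ds: WindowDataset, scheme: PoolScheme) -> np.ndarray:
    return np.array([scheme.pool_of(e) for e in ds.meta["emotion"]])


def _trial_accuracy(clf: PoolClassifier, val: WindowDataset,
                    scheme: PoolScheme) -> float:
    correct, total = 0, 0
    for _s, _t, emotion, X in val.iter_trials():
        pred, _ = clf.assign_trial(X)
        correct += int(pred == scheme.pool_of(emotion))
        total += 1
    return correct / total if total else 0.0


def train_pool_classifier(train: WindowDataset, val: WindowDataset,
                          scheme: PoolScheme, group_id: int,
                          config: Stage2Config = Stage2Config()) -> PoolClassifier:
    """Fisher-rank against pool labels, sweep fe2, train the C4.5 tree.

    The subset size maximizing trial-level pool accuracy on the
    validation set wins; ties prefer the smaller fe2.
    """
    y = pool_labels(train, scheme)
    if np.unique(y).size < 2:
        raise DomainError(
            f"group {group_id}: a pool is absent from the training data")
    ranked = rank_features(train.X, y, label_context=f"pools|{scheme.name}")
    best = None   # (acc, -fe2, classifier)
    for fe2 in config.fe2_grid:
        idx = np.sort(ranked.top(fe2))
        tree = C45Tree(min_leaf=config.min_leaf,
                       confidence=config.confidence)
        tree.fit(train.X[:, idx], y)
        clf = PoolClassifier(group_id=group_id, scheme=scheme,
                             feature_indices=idx, tree=tree, fe2=fe2)
        acc = _trial_accuracy(clf, val, scheme) if len(val) else 0.0
        clf.validation_accuracy = acc
        cand = (acc, -fe2)
        if best is None or cand > best[:2]:
            best = (acc, -fe2, clf)
    return best[2]
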