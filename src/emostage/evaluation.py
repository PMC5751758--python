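"""Leave-one-subject-out evaluation, metrics and comparison baselines.

The three-stage method is scored under leave-one-subject-out (LOSO)
cross-validation: every fold retrains all three stages on the remaining
subjects and classifies the held-out subject's trials. Baselines mirror
the standard multiclass alternatives: a single direct four-emotion
classifier on one vector per trial, and one-vs-rest / one-vs-one binary
ensembles on the per-window representation with majority-vote or
sum-rule fusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .c45 import C45Tree
from .features.extract import FeatureScaler, WindowDataset
from .recording import DomainError, EMOTIONS, map_quadrant
from .splits import (  # noqa: F401  (public evaluation surface)
    LosoFold,
    loso_folds,
    stage1_validation_split,
    stage2_validation_split,
    stage3_validation_split,
)


class LeakageError(RuntimeError):
    """A test subject's data reached a training structure."""


@dataclass
class EvaluationReport:
    """Trial-level results of one LOSO evaluation."""

    method: str
    confusion: pd.DataFrame                  # true emotion x predicted emotion
    per_stage: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return int(self.confusion.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        cm = self.confusion.to_numpy()
        return float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0

    @property
    def per_emotion_accuracy(self) -> dict[str, float]:
        out = {}
        for e in EMOTIONS:
            row = self.confusion.loc[e]
            out[e] = float(row[e] / row.sum()) if row.sum() else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accuracy": self.accuracy,
            "per_emotion_accuracy": self.per_emotion_accuracy,
            "n_trials": self.n_trials,
            "confusion": self.confusion.to_dict(),
            "per_stage": self.per_stage,
            "extras": {k: v for k, v in self.extras.items()
                       if isinstance(v, (int, float, str, list, dict))},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _empty_confusion() -> pd.DataFrame:
    return pd.DataFrame(0, index=list(EMOTIONS), columns=list(EMOTIONS))


def audit_no_leakage(test_subject: str, *training_sets: WindowDataset) -> None:
    """Raise if the held-out subject appears in any training structure."""
    for ds in training_sets:
        if test_subject in set(ds.meta["subject_id"]):
            raise LeakageError(
                f"test subject {test_subject!r} found in a training set")


def subject_agreement(ratings: pd.DataFrame) -> float:
    """Mean pairwise agreement (percent) on quadrant labels across stimuli.

    ``ratings`` has one row per (subject_id, trial_id) with valence and
    arousal; trial_id identifies the shared stimulus.
    """
    if ratings["subject_id"].nunique() < 2:
        raise DomainError("agreement needs >= 2 subjects")
    labels = ratings.assign(
        emotion=[map_quadrant(v, a)
                 for v, a in zip(ratings["valence"], ratings["arousal"])])
    per_stimulus = []
    for _t, grp in labels.groupby("trial_id"):
        lab = grp["emotion"].to_numpy()
        if lab.size < 2:
            continue
        pairs = lab.size * (lab.size - 1) / 2
        agree = sum(int(a == b) for a, b in combinations(lab, 2))
        per_stimulus.append(agree / pairs)
    if not per_stimulus:
        raise DomainError("no stimulus is rated by >= 2 subjects")
    return float(np.mean(per_stimulus)) * 100.0


# --------------------------------------------------------------------------
# three-stage LOSO driver


def evaluate_three_stage(ds: WindowDataset, config=None, seed: int = 0,
                         truth: pd.DataFrame | None = None) -> EvaluationReport:
    """LOSO evaluation of the three-stage method.

    ``truth`` (optional) carries planted per-subject groups (columns
    subject_id, group) for parameter-recovery scoring: per-fold adjusted
    Rand index of the learned subject partition and the trial-to-group
    assignment accuracy.
    """
    from sklearn.metrics import adjusted_rand_score

    from .pipeline import PipelineConfig, ThreeStageModel

    config = config or PipelineConfig()
    scheme_pool = None
    confusion = _empty_confusion()
    stage_counts = {"group_correct": 0, "group_total": 0,
                    "pool_correct": 0, "pool_total": 0}
    aris, m_values, decisions = [], [], []
    folds = loso_folds(ds.subjects)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(folds)) % (2 ** 31)

    planted = (truth.set_index("subject_id")["group"].to_dict()
               if truth is not None else None)

    for fold, fseed in zip(folds, fold_seeds):
        train = ds.select_subjects(fold.training_subjects)
        test = ds.select_subjects([fold.test_subject])
        audit_no_leakage(fold.test_subject, train)

        scaler = None
        if getattr(config, "pooled_normalization", False):
            # whole-dataset min/max, the classical (leaky) variant
            scaler = FeatureScaler().fit(ds.X, ds.missing)
        model = ThreeStageModel(config).fit(train, seed=int(fseed),
                                            scaler=scaler)
        if model.training_subjects & {fold.test_subject}:
            raise LeakageError("model trained on the held-out subject")
        scheme_pool = model.scheme
        m_values.append(model.stage1.m)

        if planted is not None:
            mapping = model.stage1.subject_to_group
            subs = sorted(mapping)
            aris.append(adjusted_rand_score(
                [planted[s] for s in subs], [mapping[s] for s in subs]))
            # expected group: where the test subject's planted peers went
            peers = [s for s in subs if planted[s] == planted[fold.test_subject]]
            expected = (int(np.bincount([mapping[s] for s in peers]).argmax())
                        if peers else None)

        for dec in model.predict_dataset(test):
            decisions.append(dec)
            true_emotion = test.meta.loc[
                (test.meta["subject_id"] == dec.subject_id)
                & (test.meta["trial_id"] == dec.trial_id), "emotion"].iloc[0]
            confusion.loc[true_emotion, dec.emotion] += 1
            stage_counts["pool_total"] += 1
            stage_counts["pool_correct"] += int(
                dec.pool == model.scheme.pool_of(true_emotion))
            if planted is not None and expected is not None:
                stage_counts["group_total"] += 1
                stage_counts["group_correct"] += int(dec.group == expected)

    per_stage = {
        "pool_accuracy": (stage_counts["pool_correct"] / stage_counts["pool_total"]
                          if stage_counts["pool_total"] else float("nan")),
        "m_step1_mode": int(pd.Series(m_values).mode().iloc[0]),
        "m_step1_per_fold": m_values,
    }
    if planted is not None:
        per_stage["group_ari_mean"] = float(np.mean(aris))
        per_stage["group_accuracy"] = (
            stage_counts["group_correct"] / stage_counts["group_total"]
            if stage_counts["group_total"] else float("nan"))
    return EvaluationReport(
        method=f"three_stage[{scheme_pool.name if scheme_pool else config.scheme}]",
        confusion=confusion, per_stage=per_stage,
        extras={"decisions": decisions})


# --------------------------------------------------------------------------
# baselines


def _trial_mean_vectors(ds: WindowDataset) -> tuple[np.ndarray, np.ndarray, list]:
    """One vector per trial: the mean of its window vectors."""
    X, y, keys = [], [], []
    for s, t, emotion, trial_X in ds.iter_trials():
        X.append(trial_X.mean(axis=0))
        y.append(emotion)
        keys.append((s, t))
    return np.vstack(X), np.array(y), keys


def _make_classifier(name: str, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "svm":
        return SVC(kernel="linear", C=200, tol=1e-3)
    if name == "c45":
        return C45Tree()
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, max_features="sqrt",
                                      random_state=seed)
    raise DomainError(f"unknown baseline classifier {name!r}")


def baseline_direct(ds: WindowDataset, classifier: str = "knn",
                    seed: int = 0) -> EvaluationReport:
    """Direct four-emotion classification, one mean vector per trial, LOSO."""
    confusion = _empty_confusion()
    for fold in loso_folds(ds.subjects):
        train = ds.select_subjects(fold.training_subjects)
        test = ds.select_subjects([fold.test_subject])
        audit_no_leakage(fold.test_subject, train)
        scaler = FeatureScaler().fit(train.X, train.missing)
        train_n = WindowDataset(scaler.transform(train.X, train.missing),
                                train.missing, train.meta, train.registry)
        test_n = WindowDataset(scaler.transform(test.X, test.missing),
                               test.missing, test.meta, test.registry)
        Xtr, ytr, _ = _trial_mean_vectors(train_n)
        Xte, yte, _ = _trial_mean_vectors(test_n)
        clf = _make_classifier(classifier, seed).fit(Xtr, ytr)
        for true, pred in zip(yte, clf.predict(Xte)):
            confusion.loc[true, pred] += 1
    return EvaluationReport(method=f"direct[{classifier}]", confusion=confusion)


def _fused_decision(votes: dict[str, float]) -> str:
    return max(EMOTIONS, key=lambda e: (votes[e], -EMOTIONS.index(e)))


def baseline_ovr(ds: WindowDataset, fusion: str = "majority_vote",
                 n_neighbors: int = 1) -> EvaluationReport:
    """One-vs-rest: 4 binary window-level classifiers fused per trial."""
    return _baseline_binary(ds, "ovr", fusion, n_neighbors)


def baseline_ovo(ds: WindowDataset, fusion: str = "majority_vote",
                 n_neighbors: int = 1) -> EvaluationReport:
    """One-vs-one: 6 binary window-level classifiers fused per trial."""
    return _baseline_binary(ds, "ovo", fusion, n_neighbors)


def _baseline_binary(ds: WindowDataset, scheme: str, fusion: str,
                     n_neighbors: int) -> EvaluationReport:
    if fusion not in ("majority_vote", "sum_rule"):
        raise DomainError(f"unknown fusion rule {fusion!r}")
    confusion = _empty_confusion()
    for fold in loso_folds(ds.subjects):
        train = ds.select_subjects(fold.training_subjects)
        test = ds.select_subjects([fold.test_subject])
        audit_no_leakage(fold.test_subject, train)
        scaler = FeatureScaler().fit(train.X, train.missing)
        Xtr = scaler.transform(train.X, train.missing)
        ytr = train.meta["emotion"].to_numpy()

        classifiers = []
        if scheme == "ovr":
            for e in EMOTIONS:
                y = np.where(ytr == e, e, "rest")
                clf = KNeighborsClassifier(n_neighbors=n_neighbors).fit(Xtr, y)
                classifiers.append((e, None, clf))
        else:
            for a, b in combinations(EMOTIONS, 2):
                mask = np.isin(ytr, (a, b))
                clf = KNeighborsClassifier(n_neighbors=n_neighbors).fit(
                    Xtr[mask], ytr[mask])
                classifiers.append((a, b, clf))

        test_n = WindowDataset(scaler.transform(test.X, test.missing),
                               test.missing, test.meta, test.registry)
        for _s, _t, true, trial_X in test_n.iter_trials():
            votes = {e: 0.0 for e in EMOTIONS}
            for a, b, clf in classifiers:
                if fusion == "majority_vote":
                    preds = clf.predict(trial_X)
                    for e in (a,) if b is None else (a, b):
                        votes[e] += float(np.sum(preds == e))
                else:
                    proba = clf.predict_proba(trial_X).sum(axis=0)
                    for e in (a,) if b is None else (a, b):
                        col = list(clf.classes_).index(e)
                        votes[e] += float(proba[col])
            confusion.loc[true, _fused_decision(votes)] += 1
    return EvaluationReport(method=f"{scheme}[{fusion}]", confusion=confusion)
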