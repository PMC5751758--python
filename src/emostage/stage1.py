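"""Stage 1: subject grouping and trial-to-group assignment.

Training (per cross-validation fold):

1. For each emotion, stack every training window with that emotion,
   label windows with subject ids, and Fisher-rank the 742 features.
2. Sweep the subset size fe1 over a grid; at each value intersect the
   four top-fe1 index sets into a candidate set FS1.
3. Pick the FS1 (and the k-NN neighbor count) that best classifies the
   validation windows by *subject*.
4. On FS1, k-means-cluster the training windows for m = 2..5 groups;
   each subject joins the group holding the majority of its windows.
   Reject m if any group ends up with fewer than a minimum number of
   subjects (extremely uneven partitions); pick the m whose group labels
   best classify the validation windows.
5. Re-rank features against the group labels and sweep fe_s1 to fix the
   final stage-1 feature subset fe_step1.

Testing: each of a trial's windows receives a k-NN probability vector
over groups (neighbor counts / k); the per-window vectors are summed
over the trial (total = window count) and the argmax group wins, ties
going to the lower group id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import KNeighborsClassifier

from .fcs import RankedFeatureList, rank_features
from .features.extract import WindowDataset
from .recording import DomainError, EMOTIONS

DEFAULT_FE_GRID = tuple(range(1, 743, 5))


@dataclass
class Stage1Config:
    fe1_grid: tuple[int, ...] = DEFAULT_FE_GRID
    fe_s1_grid: tuple[int, ...] = DEFAULT_FE_GRID
    m_grid: tuple[int, ...] = (2, 3, 4, 5)
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9)
    min_group_size: int = 3
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if not self.fe1_grid or not self.m_grid or not self.k_grid:
            raise DomainError("stage-1 grids must be non-empty")


@dataclass
class Stage1Model:
    """Trained stage-1 state: groups, feature subset and k-NN reference set."""

    feature_indices: np.ndarray          # 0-based columns, size fe_step1
    subject_to_group: dict[str, int]
    group_ids: np.ndarray
    k: int
    m: int
    fe1: int
    knn: KNeighborsClassifier = field(repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)

    def sample_probability(self, samples: np.ndarray) -> np.ndarray:
        """k-NN group probability (neighbor count / k) per sample row."""
        return self.knn.predict_proba(
            np.asarray(samples)[:, self.feature_indices])

    def assign_trial(self, trial_X: np.ndarray) -> tuple[int, np.ndarray]:
        """Sum per-window probabilities; argmax group, ties to lower id."""
        sums = self.sample_probability(trial_X).sum(axis=0)
        return int(self.group_ids[int(np.argmax(sums))]), sums


def per_emotion_subject_ranking(train: WindowDataset, emotion: str) -> RankedFeatureList:
    """Fisher-rank features for separating subjects within one emotion."""
    mask = (train.meta["emotion"] == emotion).to_numpy()
    if not mask.any():
        raise DomainError(f"emotion {emotion} absent from training set")
    subjects = train.meta.loc[mask, "subject_id"].to_numpy()
    if np.unique(subjects).size < 2:
        raise DomainError(f"need >= 2 subjects with emotion {emotion}")
    return rank_features(train.X[mask], subjects, label_context=f"subjects|{emotion}")


def intersect_top(lists: list[RankedFeatureList], fe1: int) -> np.ndarray:
    """Sorted intersection of the top-fe1 index sets of the ranked lists."""
    common = lists[0].top_set(fe1)
    for rl in lists[1:]:
        common &= rl.top_set(fe1)
    return np.array(sorted(common), dtype=int)


def _knn_accuracy(train_X, train_y, val_X, val_y, k: int) -> float:
    k = min(k, len(train_y))
    knn = KNeighborsClassifier(n_neighbors=k).fit(train_X, train_y)
    return float(np.mean(knn.predict(val_X) == val_y))


def select_fs1(train: WindowDataset, val: WindowDataset,
               config: Stage1Config) -> tuple[np.ndarray, int, int, list]:
    """Sweep fe1 (and k) maximizing subject classification on validation.

    Returns (FS1 indices, fe1, k, sweep log). Ties prefer the smaller
    fe1, then the smaller k.
    """
    present = [e for e in EMOTIONS
               if (train.meta["emotion"] == e).any()
               and train.meta.loc[train.meta["emotion"] == e, "subject_id"].nunique() >= 2]
    if not present:
        raise DomainError("no emotion with >= 2 subjects in training data")
    lists = [per_emotion_subject_ranking(train, e) for e in present]
    y_train = train.meta["subject_id"].to_numpy()
    y_val = val.meta["subject_id"].to_numpy()
    best = None   # (acc, -fe1, -k, FS1)
    log = []
    seen: set[tuple] = set()
    for fe1 in config.fe1_grid:
        fs1 = intersect_top(lists, fe1)
        if fs1.size == 0:
            continue
        key = tuple(fs1)
        if key in seen:
            continue
        seen.add(key)
        for k in config.k_grid:
            acc = _knn_accuracy(train.X[:, fs1], y_train,
                                val.X[:, fs1], y_val, k)
            log.append({"fe1": fe1, "k": k, "n_features": fs1.size, "acc": acc})
            cand = (acc, -fe1, -k)
            if best is None or cand > best[:3]:
                best = (acc, -fe1, -k, fs1)
    if best is None:
        raise DomainError("every candidate FS1 was empty")
    return best[3], -best[1], -best[2], log


def cluster_subjects(train: WindowDataset, fs1: np.ndarray, m: int,
                     seed: int, restarts: int = 10) -> dict[str, int]:
    """k-means the training windows on FS1; majority-assign each subject.

    Group ids are 1-based; a subject's windows vote and ties go to the
    lower cluster id.
    """
    if m < 2:
        raise DomainError("need at least 2 groups")
    km = KMeans(n_clusters=m, n_init=restarts, random_state=seed)
    clusters = km.fit_predict(train.X[:, fs1])
    mapping = {}
    for subj in train.subjects:
        mask = (train.meta["subject_id"] == subj).to_numpy()
        counts = np.bincount(clusters[mask], minlength=m)
        mapping[subj] = int(np.argmax(counts)) + 1
    return mapping


def _group_labels(ds: WindowDataset, mapping: dict[str, int]) -> np.ndarray:
    return ds.meta["subject_id"].map(mapping).to_numpy()


def fit_stage1(train: WindowDataset, val: WindowDataset, config: Stage1Config,
               seed: int) -> Stage1Model:
    """Run the full stage-1 training procedure on one fold."""
    fs1, fe1, k, sweep_log = select_fs1(train, val, config)

    # m sweep with evenness check
    y_val_subj = val.meta["subject_id"].to_numpy()
    best_m = None   # (acc, -m, mapping)
    for m in config.m_grid:
        if m > len(train.subjects):
            continue
        mapping = cluster_subjects(train, fs1, m, seed, config.kmeans_restarts)
        sizes = np.bincount(list(mapping.values()), minlength=m + 1)[1:]
        if (sizes < config.min_group_size).any():
            continue    # extremely uneven partition, reject this m
        y_train = _group_labels(train, mapping)
        y_val = val.meta["subject_id"].map(mapping).to_numpy()
        acc = _knn_accuracy(train.X[:, fs1], y_train, val.X[:, fs1], y_val, k)
        cand = (acc, -m)
        if best_m is None or cand > best_m[:2]:
            best_m = (acc, -m, mapping)
    if best_m is None:
        # no m passes the evenness check: fall back to m = 2
        mapping = cluster_subjects(train, fs1, 2, seed, config.kmeans_restarts)
        m_step1 = 2
    else:
        mapping = best_m[2]
        m_step1 = -best_m[1]

    # final feature sweep against group labels
    y_train = _group_labels(train, mapping)
    y_val = val.meta["subject_id"].map(mapping).to_numpy()
    if np.unique(y_train).size < 2:
        # degenerate partition (every subject in one group): nothing to
        # separate, keep the subject-selected feature set
        feature_indices = np.sort(fs1)
        fe_step1 = feature_indices.size
    else:
        ranked = rank_features(train.X, y_train, label_context="groups")
        best_fe = None   # (acc, -fe)
        for fe in config.fe_s1_grid:
            idx = ranked.top(fe)
            acc = _knn_accuracy(train.X[:, idx], y_train, val.X[:, idx], y_val, k)
            cand = (acc, -fe)
            if best_fe is None or cand > best_fe:
                best_fe = cand
        fe_step1 = -best_fe[1]
        feature_indices = np.sort(ranked.top(fe_step1))

    group_ids = np.array(sorted(set(mapping.values())))
    knn = KNeighborsClassifier(n_neighbors=min(k, len(train)))
    knn.fit(train.X[:, feature_indices], y_train)
    return Stage1Model(
        feature_indices=feature_indices, subject_to_group=mapping,
        group_ids=group_ids, k=k, m=m_step1, fe1=fe1, knn=knn,
        diagnostics={"fe_step1": fe_step1, "fs1_size": fs1.size,
                     "sweep": sweep_log, "y_val_subjects": y_val_subj})
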