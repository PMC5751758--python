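"""Stage 1: subject ranking, feature intersection, clustering, k-NN assignment.

These tests work on small hand-built feature datasets (a WindowDataset is
just a matrix plus metadata; stage operations accept any column count).
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import KNeighborsClassifier

from emostage.fcs import RankedFeatureList
from emostage.features.extract import WindowDataset
from emostage.recording import DomainError
from emostage.stage1 import (
    Stage1Config,
    Stage1Model,
    cluster_subjects,
    fit_stage1,
    intersect_top,
    per_emotion_subject_ranking,
    select_fs1,
)

RNG = np.random.default_rng(77)
EMO_CYCLE = ["EQ1", "EQ2", "EQ3", "EQ4"]


def make_blob_dataset(n_subjects=6, trials=8, windows=5, n_features=20,
                      group_shift=6.0, subject_shift=1.0, seed=0):
    """Gaussian feature blobs: planted 2 groups, subject offsets, 4 emotions."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    groups = {}
    subj_offsets = rng.normal(0, subject_shift, (n_subjects, n_features))
    for i in range(n_subjects):
        s = f"S{i + 1:02d}"
        groups[s] = i % 2 + 1
        base = subj_offsets[i] + (groups[s] - 1.5) * group_shift
        for t in range(trials):
            emotion = EMO_CYCLE[t % 4]
            for w in range(windows):
                rows.append(base + rng.normal(0, 1.0, n_features))
                meta.append({"subject_id": s, "trial_id": f"T{t + 1:02d}",
                             "emotion": emotion, "valence": 7.0 if emotion in
                             ("EQ1", "EQ2") else 3.0,
                             "arousal": 7.0 if emotion in ("EQ1", "EQ4")
                             else 3.0, "window": w})
    X = np.vstack(rows)
    ds = WindowDataset(X, np.zeros_like(X, dtype=bool), pd.DataFrame(meta))
    return ds, groups


def test_per_emotion_ranking_requires_two_subjects():
    ds, _ = make_blob_dataset(n_subjects=2)
    one = ds.select_subjects(["S01"])
    with pytest.raises(DomainError):
        per_emotion_subject_ranking(one, "EQ1")
    with pytest.raises(DomainError):
        per_emotion_subject_ranking(ds, "nonexistent")


def test_planted_subject_signature_ranks_first_in_every_emotion():
    ds, _ = make_blob_dataset(group_shift=0.0, subject_shift=0.0, seed=4)
    # plant feature 7 as the only subject-dependent feature
    subj_codes = ds.meta["subject_id"].astype("category").cat.codes.to_numpy()
    ds.X[:, 7] += subj_codes * 10.0
    for emotion in EMO_CYCLE:
        ranked = per_emotion_subject_ranking(ds, emotion)
        assert ranked.indices[0] == 7


def _ranked(order):
    order = np.asarray(order)
    return RankedFeatureList(order, np.linspace(1, 0, order.size))


def test_intersect_top_cases():
    lists = [_ranked([2, 0, 1, 3]), _ranked([2, 1, 0, 3]),
             _ranked([0, 2, 1, 3]), _ranked([1, 2, 0, 3])]
    assert 2 in intersect_top(lists, 3)
    assert np.array_equal(intersect_top(lists, 4), np.arange(4))
    disjoint = [_ranked([0, 1]), _ranked([1, 0])]
    assert intersect_top(disjoint, 1).size == 0


def test_select_fs1_single_value_grid_and_empty_error():
    ds, _ = make_blob_dataset(seed=1)
    val = ds.select_trials([(s, "T01") for s in ds.subjects])
    train = ds.drop_trials([(s, "T01") for s in ds.subjects])
    cfg = Stage1Config(fe1_grid=(5,), fe_s1_grid=(5,), k_grid=(3,),
                       min_group_size=2)
    fs1, fe1, k, log = select_fs1(train, val, cfg)
    assert fe1 == 5 and k == 3 and fs1.size > 0


def test_cluster_subjects_recovers_well_separated_groups():
    ds, groups = make_blob_dataset(group_shift=8.0, seed=2)
    mapping = cluster_subjects(ds, np.arange(20), m=2, seed=0)
    subs = sorted(mapping)
    ari = adjusted_rand_score([groups[s] for s in subs],
                              [mapping[s] for s in subs])
    assert ari == pytest.approx(1.0)


def test_cluster_subjects_majority_assignment_partitions_subjects():
    ds, _ = make_blob_dataset(seed=3)
    mapping = cluster_subjects(ds, np.arange(20), m=3, seed=0)
    assert set(mapping) == set(ds.subjects)
    assert set(mapping.values()) <= {1, 2, 3}


def test_knn_probability_is_neighbor_count_over_k():
    # reference set: 3 group-1 points and 2 group-2 points near the query
    X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [9.0], [9.5]])
    y = np.array([1, 1, 2, 1, 2, 2, 2])
    knn = KNeighborsClassifier(n_neighbors=5).fit(X, y)
    model = Stage1Model(feature_indices=np.array([0]),
                        subject_to_group={}, group_ids=np.array([1, 2]),
                        k=5, m=2, fe1=1, knn=knn)
    proba = model.sample_probability(np.array([[0.2]]))
    assert proba[0] == pytest.approx([0.6, 0.4])


def test_trial_assignment_sums_to_window_count_and_breaks_ties_low():
    X = np.array([[0.0], [1.0]])
    y = np.array([1, 2])
    knn = KNeighborsClassifier(n_neighbors=2).fit(X, y)
    model = Stage1Model(feature_indices=np.array([0]),
                        subject_to_group={}, group_ids=np.array([1, 2]),
                        k=2, m=2, fe1=1, knn=knn)
    trial = np.full((29, 1), 0.5)          # every window ties (0.5, 0.5)
    group, sums = model.assign_trial(trial)
    assert sums.sum() == pytest.approx(29.0)
    assert group == 1


def test_fit_stage1_recovers_planted_groups_and_m():
    ds, groups = make_blob_dataset(n_subjects=8, group_shift=8.0, seed=5)
    val_keys = [(s, "T01") for s in ds.subjects]
    train = ds.drop_trials(val_keys)
    val = ds.select_trials(val_keys)
    cfg = Stage1Config(fe1_grid=(4, 10, 20), fe_s1_grid=(4, 10, 20),
                       m_grid=(2, 3, 4), k_grid=(5,), min_group_size=2)
    model = fit_stage1(train, val, cfg, seed=0)
    assert model.m == 2
    subs = sorted(model.subject_to_group)
    ari = adjusted_rand_score([groups[s] for s in subs],
                              [model.subject_to_group[s] for s in subs])
    assert ari == pytest.approx(1.0)
    # held-out style check: training windows themselves classify correctly
    g, sums = model.assign_trial(train.X[:5])
    assert sums.sum() == pytest.approx(5.0)
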