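"""Stage 2 pool classification and stage 3 emotion decision."""

import numpy as np
import pandas as pd
import pytest

from emostage.c45 import C45Tree, TreeNode
from emostage.recording import DomainError
from emostage.stage2 import (
    PoolClassifier,
    PoolScheme,
    Stage2Config,
    train_pool_classifier,
)
from emostage.stage3 import Stage3Config, train_emotion_classifier
from test_stage1 import make_blob_dataset


def test_pool_schemes_partition_the_quadrants():
    ha = PoolScheme.by_name("HA_LA")
    hv = PoolScheme.by_name("HV_LV")
    assert ha.pool1 == {"EQ1", "EQ4"} and ha.pool2 == {"EQ2", "EQ3"}
    assert hv.pool1 == {"EQ1", "EQ2"} and hv.pool2 == {"EQ3", "EQ4"}
    for scheme in (ha, hv):
        assert scheme.pool1 | scheme.pool2 == {"EQ1", "EQ2", "EQ3", "EQ4"}
        assert not scheme.pool1 & scheme.pool2
        for e in ("EQ1", "EQ2", "EQ3", "EQ4"):
            assert scheme.pool_of(e) in (1, 2)
    with pytest.raises(DomainError):
        PoolScheme.by_name("bogus")


def _stub_classifier():
    """Tree whose two leaves produce path probabilities (0.6,0.4) / (0.1,0.9)."""
    tree = C45Tree()
    tree.classes_ = np.array([1, 2])
    left = TreeNode(distribution=np.array([1.0, 0.0]), counts=np.array([1.0, 0.0]))
    right = TreeNode(distribution=np.array([0.0, 1.0]), counts=np.array([0.0, 1.0]))
    tree.root = TreeNode(distribution=np.array([0.2, 0.8]),
                         counts=np.array([2.0, 8.0]),
                         feature=0, threshold=0.0, left=left, right=right)
    return PoolClassifier(group_id=1, scheme=PoolScheme.by_name("HA_LA"),
                          feature_indices=np.array([0]), tree=tree)


def test_trial_pool_aggregation_hand_arithmetic():
    clf = _stub_classifier()
    trial = np.concatenate([np.full((20, 1), -1.0), np.full((9, 1), +1.0)])
    pool, sums = clf.assign_trial(trial)
    assert sums == pytest.approx([20 * 0.6 + 9 * 0.1, 20 * 0.4 + 9 * 0.9])
    assert sums.sum() == pytest.approx(29.0)
    assert pool == 2


def test_unanimous_windows_give_full_sum():
    clf = _stub_classifier()
    pool, sums = clf.assign_trial(np.full((29, 1), -1.0))
    assert pool == 1
    assert sums == pytest.approx([29 * 0.6, 29 * 0.4])


def _arousal_dataset(seed=0, n_subjects=4):
    """Feature-level dataset where only arousal-linked columns carry signal."""
    ds, _ = make_blob_dataset(n_subjects=n_subjects, trials=8, windows=5,
                              group_shift=0.0, subject_shift=0.0, seed=seed)
    ha = ds.meta["emotion"].isin(["EQ1", "EQ4"]).to_numpy()
    ds.X[:, :4] += np.where(ha, 3.0, -3.0)[:, None]
    return ds


def test_separable_pools_reach_perfect_validation_accuracy():
    ds = _arousal_dataset()
    val_keys = [(s, "T01") for s in ds.subjects]
    clf = train_pool_classifier(ds.drop_trials(val_keys),
                                ds.select_trials(val_keys),
                                PoolScheme.by_name("HA_LA"), group_id=1,
                                config=Stage2Config(fe2_grid=(2, 6)))
    assert clf.validation_accuracy == 1.0
    assert set(clf.feature_indices[:2]) <= {0, 1, 2, 3}


def test_arousal_only_signal_favors_ha_la_pooling():
    ds = _arousal_dataset(seed=9)
    val_keys = [(s, t) for s in ds.subjects for t in ("T01", "T02")]
    train, val = ds.drop_trials(val_keys), ds.select_trials(val_keys)
    accs = {}
    for name in ("HA_LA", "HV_LV"):
        clf = train_pool_classifier(train, val, PoolScheme.by_name(name),
                                    group_id=1,
                                    config=Stage2Config(fe2_grid=(2, 6, 12)))
        accs[name] = clf.validation_accuracy
    assert accs["HA_LA"] > accs["HV_LV"]


def test_missing_pool_is_a_domain_error():
    ds = _arousal_dataset()
    only_ha = ds.mask(ds.meta["emotion"].isin(["EQ1", "EQ4"]).to_numpy())
    with pytest.raises(DomainError):
        train_pool_classifier(only_ha, only_ha, PoolScheme.by_name("HA_LA"),
                              group_id=1, config=Stage2Config(fe2_grid=(2,)))


def _emotion_dataset(seed=0):
    """EQ1 vs EQ4 separable on feature 5."""
    ds, _ = make_blob_dataset(n_subjects=4, trials=8, windows=5,
                              group_shift=0.0, subject_shift=0.0, seed=seed)
    pool = ds.mask(ds.meta["emotion"].isin(["EQ1", "EQ4"]).to_numpy())
    eq1 = (pool.meta["emotion"] == "EQ1").to_numpy()
    pool.X[:, 5] += np.where(eq1, 4.0, -4.0)
    return pool


def test_emotion_classifier_decides_by_window_majority():
    pool = _emotion_dataset()
    val_keys = [(s, "T01") for s in pool.subjects]
    clf = train_emotion_classifier(pool.drop_trials(val_keys),
                                   pool.select_trials(val_keys),
                                   group_id=1, pool_id=1,
                                   emotions=("EQ1", "EQ4"), seed=3,
                                   config=Stage3Config(fe3_grid=(2, 6),
                                                       n_trees=30))
    assert clf.validation_accuracy == 1.0
    trial = pool.select_trials([(pool.subjects[0], "T04")])   # an EQ4 trial
    emotion, votes = clf.decide_trial(trial.X)
    assert sum(votes.values()) == trial.X.shape[0]
    assert emotion == trial.meta["emotion"].iloc[0]


def test_same_seed_reproduces_identical_decisions():
    pool = _emotion_dataset(seed=2)
    val_keys = [(s, "T01") for s in pool.subjects]
    args = (pool.drop_trials(val_keys), pool.select_trials(val_keys))
    kwargs = dict(group_id=1, pool_id=1, emotions=("EQ1", "EQ4"), seed=9,
                  config=Stage3Config(fe3_grid=(4,), n_trees=25))
    a = train_emotion_classifier(*args, **kwargs)
    b = train_emotion_classifier(*args, **kwargs)
    X = pool.X[:40]
    assert np.array_equal(a.forest.predict(X[:, a.feature_indices]),
                          b.forest.predict(X[:, b.feature_indices]))


def test_tie_between_emotions_goes_to_lower_quadrant():
    pool = _emotion_dataset(seed=5)
    val_keys = [(s, "T01") for s in pool.subjects]
    clf = train_emotion_classifier(pool.drop_trials(val_keys),
                                   pool.select_trials(val_keys),
                                   group_id=1, pool_id=1,
                                   emotions=("EQ1", "EQ4"), seed=1,
                                   config=Stage3Config(fe3_grid=(6,),
                                                       n_trees=30))
    eq1_rows = pool.X[(pool.meta["emotion"] == "EQ1").to_numpy()][:1]
    eq4_rows = pool.X[(pool.meta["emotion"] == "EQ4").to_numpy()][:1]
    two_rows = np.vstack([eq1_rows, eq4_rows])     # one vote each
    emotion, votes = clf.decide_trial(two_rows)
    if votes["EQ1"] == votes["EQ4"]:
        assert emotion == "EQ1"
    else:   # forest mapped both rows to one side; majority rule applies
        assert emotion == max(votes, key=votes.get)
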