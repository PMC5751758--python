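"""LOSO folds, per-stage validation construction, agreement and report metrics."""

import numpy as np
import pandas as pd
import pytest

from emostage.evaluation import (
    LeakageError,
    audit_no_leakage,
    baseline_direct,
    baseline_ovo,
    baseline_ovr,
    subject_agreement,
)
from emostage.features.extract import WindowDataset
from emostage.recording import DomainError
from emostage.splits import (
    loso_folds,
    stage1_validation_split,
    stage2_validation_split,
    stage3_validation_split,
)
from test_stage1 import make_blob_dataset


def test_loso_folds_cover_every_subject_once():
    subjects = [f"S{i:02d}" for i in range(1, 33)]
    folds = loso_folds(subjects)
    assert len(folds) == 32
    assert all(len(f.training_subjects) == 31 for f in folds)
    assert sorted(f.test_subject for f in folds) == subjects
    for f in folds:
        assert f.test_subject not in f.training_subjects
    with pytest.raises(DomainError):
        loso_folds(["only"])


def _trials_frame(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    rows = []
    for subj, emotions in counts.items():
        i = 0
        for emotion, n in emotions.items():
            for _ in range(n):
                i += 1
                rows.append({"subject_id": subj, "trial_id": f"T{i:02d}",
                             "emotion": emotion})
    return pd.DataFrame(rows)


def test_stage1_split_takes_one_trial_per_subject():
    trials = _trials_frame({
        f"S{i:02d}": {"EQ1": 3, "EQ2": 2, "EQ3": 2, "EQ4": 1}
        for i in range(1, 9)})
    val = stage1_validation_split(trials, np.random.default_rng(0))
    assert len(val) == 8
    assert len({s for s, _t in val}) == 8
    # a subject's single EQ4 trial must stay in training
    chosen_emotions = {s: trials.set_index(["subject_id", "trial_id"])
                       .loc[(s, t), "emotion"] for s, t in val}
    assert all(e != "EQ4" for e in chosen_emotions.values())


def test_stage2_split_strict_threshold_and_ladder():
    trials = _trials_frame({
        "S01": {"EQ1": 6, "EQ2": 2, "EQ3": 2, "EQ4": 2},
        "S02": {"EQ1": 5, "EQ2": 6, "EQ3": 2, "EQ4": 2},
        "S03": {"EQ1": 2, "EQ2": 2, "EQ3": 6, "EQ4": 6},
    })
    val = stage2_validation_split(trials, np.random.default_rng(1))
    picked = trials.set_index(["subject_id", "trial_id"]).loc[
        [(s, t) for s, t in val], "emotion"]
    # S01 has 6 EQ1 trials -> exactly one; S02 has only 5 -> none of its EQ1
    eq1 = picked[picked == "EQ1"]
    assert len(eq1) == 1 and eq1.index[0][0] == "S01"
    # every emotion present in validation via the ladder
    assert set(picked) == {"EQ1", "EQ2", "EQ3", "EQ4"}
    # train/validation are disjoint by construction
    assert len(set(val)) == len(val)


def test_stage3_split_threshold_and_fallback():
    trials = _trials_frame({
        "S01": {"EQ1": 5, "EQ4": 3},
        "S02": {"EQ1": 3, "EQ4": 4},     # nobody exceeds 4 EQ4 trials
    })
    val = stage3_validation_split(trials, np.random.default_rng(2),
                                  emotions=("EQ1", "EQ4"))
    picked = trials.set_index(["subject_id", "trial_id"]).loc[
        [(s, t) for s, t in val], "emotion"]
    assert (picked == "EQ1").sum() == 1          # S01 exceeds 4
    assert (picked == "EQ4").sum() == 1          # fallback >3 catches S02
    assert {s for s, _ in val} == {"S01", "S02"}


def test_splits_are_deterministic_given_the_seed():
    trials = _trials_frame({
        f"S{i:02d}": {"EQ1": 6, "EQ2": 6, "EQ3": 3, "EQ4": 3}
        for i in range(1, 6)})
    a = stage2_validation_split(trials, np.random.default_rng(42))
    b = stage2_validation_split(trials, np.random.default_rng(42))
    assert a == b


def test_subject_agreement_extremes_and_random_rate():
    def panel(labels_by_subject):
        rows = []
        for s, labels in labels_by_subject.items():
            for t, (v, a) in enumerate(labels):
                rows.append({"subject_id": s, "trial_id": f"T{t}",
                             "valence": v, "arousal": a})
        return pd.DataFrame(rows)

    full = panel({"A": [(7, 7), (3, 3)], "B": [(8, 6), (2, 2)]})
    assert subject_agreement(full) == pytest.approx(100.0)

    half = panel({"A": [(7, 7), (3, 3)], "B": [(8, 6), (7, 7)]})
    assert subject_agreement(half) == pytest.approx(50.0)

    rng = np.random.default_rng(5)
    quadrant_centers = {"EQ1": (7, 7), "EQ2": (7, 3), "EQ3": (3, 3), "EQ4": (3, 7)}
    rows = []
    for s in "ABCDE":
        for t in range(800):
            v, a = quadrant_centers[rng.choice(list(quadrant_centers))]
            rows.append({"subject_id": s, "trial_id": f"T{t}",
                         "valence": v, "arousal": a})
    assert subject_agreement(pd.DataFrame(rows)) == pytest.approx(25.0, abs=3.0)


def test_leakage_audit_detects_contamination():
    ds, _ = make_blob_dataset(n_subjects=3, trials=4, windows=2)
    audit_no_leakage("S99", ds)
    with pytest.raises(LeakageError):
        audit_no_leakage("S01", ds)


def _separable_dataset(seed=0):
    ds, _ = make_blob_dataset(n_subjects=4, trials=8, windows=5,
                              group_shift=0.0, subject_shift=0.0, seed=seed)
    # wide separation so even window-level 1-NN in the full feature space
    # (including the pure-noise columns) resolves the four classes
    centers = {"EQ1": (9, 0), "EQ2": (0, 9), "EQ3": (-9, 0), "EQ4": (0, -9)}
    for e, (c0, c1) in centers.items():
        m = (ds.meta["emotion"] == e).to_numpy()
        ds.X[m, 0] += c0
        ds.X[m, 1] += c1
    return ds


@pytest.mark.parametrize("runner", [
    lambda ds: baseline_direct(ds, "knn"),
    lambda ds: baseline_ovr(ds, "majority_vote"),
    lambda ds: baseline_ovr(ds, "sum_rule"),
    lambda ds: baseline_ovo(ds, "majority_vote"),
    lambda ds: baseline_ovo(ds, "sum_rule"),
])
def test_baselines_solve_separable_emotions(runner):
    report = runner(_separable_dataset())
    assert report.accuracy == 1.0
    cm = report.confusion
    # rows sum to the per-emotion trial counts (4 subjects x 2 trials each)
    assert (cm.sum(axis=1) == 8).all()
    assert report.n_trials == 32


def test_direct_baseline_uses_one_sample_per_trial():
    ds = _separable_dataset(seed=1)
    report = baseline_direct(ds, "svm")
    assert report.n_trials == len(ds.trials())


def test_permuted_labels_fall_to_chance():
    rng = np.random.default_rng(9)
    ds = _separable_dataset(seed=2)
    shuffled = ds.meta.copy()
    for s in ds.subjects:
        m = shuffled["subject_id"] == s
        trials = shuffled.loc[m, "trial_id"].unique()
        emap = dict(zip(trials, rng.permutation(
            [shuffled.loc[m & (shuffled["trial_id"] == t), "emotion"].iloc[0]
             for t in trials])))
        shuffled.loc[m, "emotion"] = shuffled.loc[m, "trial_id"].map(emap)
    ds_perm = WindowDataset(ds.X, ds.missing, shuffled)
    report = baseline_direct(ds_perm, "knn")
    assert report.accuracy < 0.55          # 0.25 chance plus small-sample noise
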