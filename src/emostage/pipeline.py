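"""The three-stage decision model: grouping, pooling, emotion.

``ThreeStageModel.fit`` runs the full training procedure on one fold's
training subjects (normalization, stage-1 grouping, per-group stage-2
pool classifiers, per-pool stage-3 forests); ``predict`` walks a test
trial through the three decisions and returns the full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .splits import (
    stage1_validation_split,
    stage2_validation_split,
    stage3_validation_split,
)
from .features.extract import FeatureScaler, WindowDataset
from .recording import DomainError
from .stage1 import Stage1Config, Stage1Model, fit_stage1
from .stage2 import PoolClassifier, PoolScheme, Stage2Config, train_pool_classifier
from .stage3 import EmotionClassifier, Stage3Config, train_emotion_classifier


@dataclass
class PipelineConfig:
    scheme: str = "HA_LA"
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    stage3: Stage3Config = field(default_factory=Stage3Config)
    pooled_normalization: bool = False


@dataclass
class TrialDecision:
    """Decision provenance for one test trial."""

    subject_id: str
    trial_id: str
    group: int
    group_sums: np.ndarray
    pool: int
    pool_sums: np.ndarray
    emotion: str
    votes: dict[str, int]


class ThreeStageModel:
    """Trained three-stage decision model for one training population."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.scheme = PoolScheme.by_name(self.config.scheme)
        self.scaler: FeatureScaler | None = None
        self.stage1: Stage1Model | None = None
        self.pool_classifiers: dict[int, PoolClassifier] = {}
        self.emotion_classifiers: dict[tuple[int, int], EmotionClassifier] = {}
        self.training_subjects: set[str] = set()

    # -- training -----------------------------------------------------------

    def fit(self, train: WindowDataset, seed: int,
            scaler: FeatureScaler | None = None) -> "ThreeStageModel":
        """Train all three stages on one fold's training subjects.

        ``scaler`` may be supplied pre-fitted (pooled normalization);
        by default it is fitted on the training windows only.
        """
        if len(train.subjects) < 2:
            raise DomainError("training data must span >= 2 subjects")
        self.training_subjects = set(train.subjects)
        ss = np.random.SeedSequence(seed)
        seeds = ss.generate_state(8) % (2 ** 31)
        rng = np.random.default_rng(seeds[0])

        if scaler is None:
            scaler = FeatureScaler().fit(train.X, train.missing)
        self.scaler = scaler
        norm = WindowDataset(scaler.transform(train.X, train.missing),
                             np.zeros_like(train.missing), train.meta,
                             train.registry)

        # stage 1: subject grouping
        trials = norm.trials()
        val_keys = stage1_validation_split(trials, rng)
        train1 = norm.drop_trials(val_keys)
        val1 = norm.select_trials(val_keys)
        self.stage1 = fit_stage1(train1, val1, self.config.stage1,
                                 seed=int(seeds[1]))

        # stages 2 and 3 operate per group on the full training data
        mapping = self.stage1.subject_to_group
        for gi, g in enumerate(sorted(set(mapping.values()))):
            members = [s for s, grp in mapping.items() if grp == g]
            group_ds = norm.select_subjects(members)
            g_trials = group_ds.trials()
            val2_keys = stage2_validation_split(g_trials, rng)
            self.pool_classifiers[g] = train_pool_classifier(
                group_ds.drop_trials(val2_keys),
                group_ds.select_trials(val2_keys),
                self.scheme, g, self.config.stage2)
            for pool in (1, 2):
                emotions = self.scheme.emotions(pool)
                pool_mask = group_ds.meta["emotion"].isin(emotions).to_numpy()
                pool_ds = group_ds.mask(pool_mask)
                p_trials = pool_ds.trials()
                val3_keys = stage3_validation_split(p_trials, rng, emotions)
                self.emotion_classifiers[(g, pool)] = train_emotion_classifier(
                    pool_ds.drop_trials(val3_keys),
                    pool_ds.select_trials(val3_keys),
                    g, pool, emotions,
                    seed=int(seeds[2] + 31 * gi + pool),
                    config=self.config.stage3)
        return self

    # -- prediction ---------------------------------------------------------

    def predict_trial(self, trial_X: np.ndarray,
                      trial_missing: np.ndarray | None = None,
                      subject_id: str = "?", trial_id: str = "?") -> TrialDecision:
        """Classify one trial (windows x 742, channel-native scale)."""
        if self.stage1 is None:
            raise RuntimeError("model is not fitted")
        X = self.scaler.transform(np.asarray(trial_X, dtype=float),
                                  trial_missing)
        group, group_sums = self.stage1.assign_trial(X)
        pool, pool_sums = self.pool_classifiers[group].assign_trial(X)
        emotion, votes = self.emotion_classifiers[(group, pool)].decide_trial(X)
        return TrialDecision(subject_id, trial_id, group, group_sums,
                             pool, pool_sums, emotion, votes)

    def predict_dataset(self, ds: WindowDataset) -> list[TrialDecision]:
        out = []
        for s, t, _e, X in ds.iter_trials():
            idx = ((ds.meta["subject_id"] == s)
                   & (ds.meta["trial_id"] == t)).to_numpy()
            out.append(self.predict_trial(X, ds.missing[idx], s, t))
        return out
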