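"""Window-level extraction, dataset assembly and [0,1] normalization.

A 60 s trial produces 29 windows x 742 features; a whole study (32
subjects x 17 trials) produces a 15,776 x 742 matrix. Columns are
min-max normalized to [0,1] on the training portion only by default
(``pooled`` restores whole-dataset normalization, which leaks test
statistics and exists for strict procedure reproduction only).
Features that cannot be computed
in a window (too few beats or breaths) are flagged missing and imputed
with the training-set column median before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..channels import ASYMMETRY_PAIRS, EEG_CHANNELS, PERIPHERAL_CHANNELS
from ..recording import DomainError, FormatError, Recording, Window
from . import blocks
from .registry import REGISTRY, FeatureRegistry


def extract_window(window_signal: np.ndarray, channels: tuple[str, ...],
                   fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Compute the full 742-feature vector for one window.

    ``window_signal`` is channels x samples with rows ordered as
    ``channels`` (which must contain the canonical 40 labels). Returns
    (values, missing_mask).
    """
    idx = {}
    for ch in EEG_CHANNELS + PERIPHERAL_CHANNELS:
        if ch not in channels:
            raise FormatError(f"channel {ch!r} missing from recording")
        idx[ch] = channels.index(ch)

    values = np.zeros(742)
    missing = np.zeros(742, dtype=bool)
    pos = 0

    band_psd = {}
    nonlin = {}
    for ch in EEG_CHANNELS:
        tf, bands, nl = blocks._eeg_channel(window_signal[idx[ch]], fs)
        values[pos:pos + 14] = tf
        pos += 14
        band_psd[ch] = bands
        nonlin[ch] = nl

    for left, right in ASYMMETRY_PAIRS:
        values[pos:pos + 4] = blocks.hemispheric_asymmetry(
            band_psd[left], band_psd[right])
        pos += 4

    for ch in EEG_CHANNELS:
        values[pos:pos + 3] = nonlin[ch]
        pos += 3

    for ch in ("hEOG", "vEOG"):
        values[pos:pos + 4] = blocks.eog_features(window_signal[idx[ch]])
        pos += 4
    for ch in ("EMG1", "EMG2"):
        values[pos:pos + 17] = blocks.emg_features(window_signal[idx[ch]], fs)
        pos += 17

    values[pos:pos + 4] = blocks.tmp_features(window_signal[idx["TMP"]], fs)
    pos += 4
    values[pos:pos + 20], missing[pos:pos + 20] = blocks.bvp_features(
        window_signal[idx["BVP"]], fs)
    pos += 20
    values[pos:pos + 55], missing[pos:pos + 55] = blocks.rsp_features(
        window_signal[idx["RSP"]], fs)
    pos += 55
    values[pos:pos + 21] = blocks.gsr_features(window_signal[idx["GSR"]], fs)
    pos += 21
    assert pos == 742
    return values, missing


@dataclass
class TrialFeatureMatrix:
    """Windows x 742 feature representation of one trial."""

    subject_id: str
    trial_id: str
    emotion: str
    valence: float
    arousal: float
    values: np.ndarray           # (n_windows, 742)
    missing: np.ndarray          # bool, same shape

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def extract_trial(recording: Recording, window: Window = Window(),
                  max_duration: float | None = 60.0) -> TrialFeatureMatrix:
    """Segment a recording and extract one feature vector per window."""
    from ..recording import segment

    slices = segment(recording, window, max_duration=max_duration)
    vals = np.empty((len(slices), 742))
    miss = np.empty((len(slices), 742), dtype=bool)
    for i, sl in enumerate(slices):
        vals[i], miss[i] = extract_window(sl, recording.channels,
                                          recording.sampling_rate)
    return TrialFeatureMatrix(recording.subject_id, recording.trial_id,
                              recording.emotion, recording.valence,
                              recording.arousal, vals, miss)


@dataclass
class WindowDataset:
    """All windows of a study: feature matrix plus per-window metadata.

    ``meta`` has one row per window with columns subject_id, trial_id,
    emotion, valence, arousal, window.
    """

    X: np.ndarray
    missing: np.ndarray
    meta: pd.DataFrame
    registry: FeatureRegistry = field(default=REGISTRY, repr=False)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.meta):
            raise ValueError("feature matrix and metadata row counts differ")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.meta["subject_id"].unique())

    def trials(self) -> pd.DataFrame:
        """One row per trial (subject_id, trial_id, emotion, valence, arousal)."""
        return (self.meta
                .drop_duplicates(["subject_id", "trial_id"])
                [["subject_id", "trial_id", "emotion", "valence", "arousal"]]
                .reset_index(drop=True))

    def mask(self, row_mask: np.ndarray) -> "WindowDataset":
        row_mask = np.asarray(row_mask)
        return WindowDataset(self.X[row_mask], self.missing[row_mask],
                             self.meta.loc[row_mask].reset_index(drop=True),
                             self.registry)

    def select_subjects(self, subjects) -> "WindowDataset":
        return self.mask(self.meta["subject_id"].isin(set(subjects)).to_numpy())

    def select_trials(self, trial_keys) -> "WindowDataset":
        keys = set(map(tuple, trial_keys))
        m = [(s, t) in keys for s, t in
             zip(self.meta["subject_id"], self.meta["trial_id"])]
        return self.mask(np.array(m))

    def drop_trials(self, trial_keys) -> "WindowDataset":
        keys = set(map(tuple, trial_keys))
        m = [(s, t) not in keys for s, t in
             zip(self.meta["subject_id"], self.meta["trial_id"])]
        return self.mask(np.array(m))

    def iter_trials(self):
        """Yield (subject_id, trial_id, emotion, X_trial) per trial."""
        for (s, t), grp in self.meta.groupby(["subject_id", "trial_id"],
                                             sort=True):
            yield s, t, grp["emotion"].iloc[0], self.X[grp.index.to_numpy()]


def extract_dataset(recordings, window: Window = Window(),
                    max_duration: float | None = 60.0) -> WindowDataset:
    """Extract and stack features for a list of recordings."""
    mats = [extract_trial(r, window, max_duration) for r in recordings]
    X = np.vstack([m.values for m in mats])
    miss = np.vstack([m.missing for m in mats])
    meta = pd.DataFrame([
        {"subject_id": m.subject_id, "trial_id": m.trial_id,
         "emotion": m.emotion, "valence": m.valence, "arousal": m.arousal,
         "window": w}
        for m in mats for w in range(m.n_windows)
    ])
    return WindowDataset(X, miss, meta)


class FeatureScaler:
    """Median imputation of missing cells plus per-column [0,1] min-max scaling.

    Fitted on training data only; applying the fitted affine map to other
    matrices may produce values outside [0,1]. Constant training columns
    map to 0.
    """

    def __init__(self) -> None:
        self.medians_: np.ndarray | None = None
        self.mins_: np.ndarray | None = None
        self.maxs_: np.ndarray | None = None

    def fit(self, X: np.ndarray, missing: np.ndarray | None = None) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise DomainError("cannot fit scaler on an empty matrix")
        if missing is None:
            missing = np.zeros_like(X, dtype=bool)
        masked = np.where(missing, np.nan, X)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(masked, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        filled = np.where(missing, med[None, :], X)
        self.medians_ = med
        self.mins_ = filled.min(axis=0)
        self.maxs_ = filled.max(axis=0)
        return self

    def transform(self, X: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
        if self.medians_ is None:
            raise RuntimeError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        if missing is not None:
            X = np.where(missing, self.medians_[None, :], X)
        span = self.maxs_ - self.mins_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.mins_[nz]) / span[nz]
        return out

    def fit_transform(self, X: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, missing).transform(X, missing)


def normalize_columns(train: np.ndarray, *others: np.ndarray,
                      train_missing: np.ndarray | None = None,
                      pooled: bool = False):
    """Min-max normalize columns to [0,1] using the training matrix.

    Returns (normalized matrices..., (mins, maxs)). With ``pooled`` the
    min/max are taken over the stack of all matrices at once — the
    classical whole-dataset normalization, which leaks test statistics
    and is off by default.
    """
    scaler = FeatureScaler()
    if pooled and others:
        scaler.fit(np.vstack((train,) + others))
    else:
        scaler.fit(train, train_missing)
    out = [scaler.transform(train, train_missing)]
    out.extend(scaler.transform(o) for o in others)
    return (*out, (scaler.mins_, scaler.maxs_))
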