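"""Synthetic multi-subject physiological recordings with planted effects.

The generator emulates the study conditions the pipeline is built for:
32 subjects x 17 one-minute trials of 40 channels (32 EEG + 8
peripheral) with per-trial valence/arousal self-ratings. Three planted
effects make every stage of the method testable without real data:

* **group structure** — subjects belong to one of ``n_groups`` groups
  whose broadband EEG baseline power is shifted (log domain) by
  ``group_effect``, i.e. the dominant axis of inter-individual
  variation is a spectral baseline signature;
* **arousal** — high-arousal trials gain beta/gamma EEG power, heart
  rate and phasic skin-conductance activity (``arousal_effect``);
* **valence** — high-valence trials shift frontal alpha power toward
  the right hemisphere (``valence_effect``), low valence the reverse.

Subjects additionally carry idiosyncratic spectral signatures and
peripheral baselines (``subject_sd``) so subject identification — the
raw material of stage 1 — is possible. Each stimulus has an intended
quadrant; a subject *feels* that quadrant with probability
``rating_agreement`` (else one of the other three), physiological
effects and self-ratings both follow the felt emotion, which makes the
panel's mean pairwise quadrant agreement land near the ~75% regime seen
in human affect panels. All randomness flows from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import (
    ALL_CHANNELS,
    ASYMMETRY_PAIRS,
    CENTRAL,
    EEG_CHANNELS,
    FRONTAL,
)
from .recording import DomainError, EMOTIONS, Recording, map_quadrant

# band plateaus added on top of the pink base (power units, log-shifted)
_BAND_EDGES = {"theta": (4.0, 7.0), "alpha": (8.0, 15.0),
               "beta": (16.0, 31.0), "gamma": (32.0, 45.0)}
_BAND_BASE_POWER = {"theta": 2.0, "alpha": 3.0, "beta": 1.5, "gamma": 0.8}
_VALENCE_PAIRS = ASYMMETRY_PAIRS[:4]     # frontal pairs carry the asymmetry


@dataclass
class SynthConfig:
    n_subjects: int = 32
    trials_per_subject: int = 17
    duration: float = 60.0
    sampling_rate: float = 128.0
    n_groups: int = 2
    group_effect: float = 1.0
    arousal_effect: float = 0.5
    valence_effect: float = 0.4
    noise_sd: float = 1.0
    subject_sd: float = 0.35
    rating_agreement: float = 0.86
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise DomainError("need at least one subject and one trial")
        if self.n_groups < 1 or self.n_groups > self.n_subjects:
            raise DomainError("n_groups must be in [1, n_subjects]")
        if min(self.group_effect, self.arousal_effect, self.valence_effect,
               self.noise_sd, self.subject_sd) < 0:
            raise DomainError("effect sizes and noise scales must be >= 0")
        if not (0.0 <= self.rating_agreement <= 1.0):
            raise DomainError("rating_agreement must be a probability")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise DomainError("duration and sampling_rate must be positive")


def _region(ch: str) -> int:
    if ch in FRONTAL:
        return 0
    if ch in CENTRAL:
        return 1
    return 2


@dataclass
class _Plan:
    subjects: list[str]
    trials: list[str]
    groups: dict[str, int]
    band_offsets: np.ndarray          # (subject, band, region) log offsets
    hr_base: np.ndarray
    gsr_base: np.ndarray
    rsp_rate: np.ndarray
    tmp_base: np.ndarray
    felt: dict[tuple[str, str], str]
    ratings: dict[tuple[str, str], tuple[float, float]]


def _make_plan(config: SynthConfig) -> _Plan:
    ss = np.random.SeedSequence([config.seed, 0x5EED])
    rng = np.random.default_rng(ss)
    ns, nt = config.n_subjects, config.trials_per_subject
    subjects = [f"S{i + 1:02d}" for i in range(ns)]
    trials = [f"T{j + 1:02d}" for j in range(nt)]
    groups = {s: (i % config.n_groups) + 1 for i, s in enumerate(subjects)}
    band_offsets = rng.normal(0.0, config.subject_sd, size=(ns, 4, 3))
    hr_base = 62.0 + rng.normal(0, 4, ns)
    gsr_base = 6.0 + rng.normal(0, 1.5, ns)
    rsp_rate = np.clip(0.25 + rng.normal(0, 0.03, ns), 0.15, 0.4)
    tmp_base = 33.0 + rng.normal(0, 0.4, ns)

    intended = np.resize(EMOTIONS, nt)    # balanced up to rounding
    felt, ratings = {}, {}
    for s in subjects:
        for j, t in enumerate(trials):
            q = intended[j]
            if rng.random() > config.rating_agreement:
                q = rng.choice([e for e in EMOTIONS if e != q])
            hv = q in ("EQ1", "EQ2")
            ha = q in ("EQ1", "EQ4")
            val = rng.uniform(5.6, 8.7) if hv else rng.uniform(1.3, 4.4)
            aro = rng.uniform(5.6, 8.7) if ha else rng.uniform(1.3, 4.4)
            felt[(s, t)] = q
            ratings[(s, t)] = (float(val), float(aro))
    return _Plan(subjects, trials, groups, band_offsets, hr_base, gsr_base,
                 rsp_rate, tmp_base, felt, ratings)


def ground_truth(config: SynthConfig) -> pd.DataFrame:
    """Planted per-trial labels: subject, trial, group, emotion, ratings."""
    plan = _make_plan(config)
    rows = []
    for s in plan.subjects:
        for t in plan.trials:
            val, aro = plan.ratings[(s, t)]
            rows.append({"subject_id": s, "trial_id": t,
                         "group": plan.groups[s],
                         "emotion": plan.felt[(s, t)],
                         "valence": val, "arousal": aro})
    df = pd.DataFrame(rows)
    assert all(map_quadrant(v, a) == e for v, a, e in
               zip(df["valence"], df["arousal"], df["emotion"]))
    return df


def _smooth_noise(rng, n: int, fs: float, window_s: float = 1.0) -> np.ndarray:
    w = rng.standard_normal(n)
    k = max(1, int(window_s * fs))
    sm = np.convolve(w, np.ones(k) / k, mode="same")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _eeg_channel_signal(rng, n: int, fs: float, band_log_offsets: dict[str, float],
                        noise_sd: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = noise_sd ** 2 / (1.0 + freqs)          # pink-ish broadband base
    for band, (lo, hi) in _BAND_EDGES.items():
        mask = (freqs >= lo) & (freqs < hi)
        psd[mask] += _BAND_BASE_POWER[band] * np.exp(band_log_offsets[band])
    spec = np.sqrt(psd) * (rng.standard_normal(freqs.size)
                           + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x * np.sqrt(n / 2.0)


def _phasic_kernel(t: np.ndarray, onset: float, amp: float) -> np.ndarray:
    dt = t - onset
    out = np.zeros_like(t)
    m = dt > 0
    out[m] = amp * (1 - np.exp(-dt[m] / 0.7)) * np.exp(-dt[m] / 3.0)
    return out


def _generate_trial(rng, config: SynthConfig, plan: _Plan, si: int,
                    subject: str, trial: str) -> Recording:
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    q = plan.felt[(subject, trial)]
    hv = q in ("EQ1", "EQ2")
    ha = q in ("EQ1", "EQ4")
    a_sign = 0.5 if ha else -0.5
    v_sign = 0.5 if hv else -0.5
    group = plan.groups[subject]
    g_centered = (group - 1) - (config.n_groups - 1) / 2.0

    right_valence = {r for _l, r in _VALENCE_PAIRS}
    left_valence = {l for l, _r in _VALENCE_PAIRS}

    signal = np.empty((len(ALL_CHANNELS), n))
    for ci, ch in enumerate(EEG_CHANNELS):
        reg = _region(ch)
        offs = {band: plan.band_offsets[si, bi, reg]
                + config.group_effect * g_centered
                for bi, band in enumerate(_BAND_EDGES)}
        offs["beta"] += config.arousal_effect * a_sign
        offs["gamma"] += config.arousal_effect * a_sign
        if ch in right_valence:
            offs["alpha"] += config.valence_effect * v_sign
        elif ch in left_valence:
            offs["alpha"] -= config.valence_effect * v_sign
        signal[ci] = _eeg_channel_signal(rng, n, fs, offs, config.noise_sd)

    idx = {ch: len(EEG_CHANNELS) + k
           for k, ch in enumerate(ALL_CHANNELS[len(EEG_CHANNELS):])}

    # skin conductance: tonic level + drift + arousal-dependent phasic events
    tonic = (plan.gsr_base[si] + 0.5 * config.arousal_effect * a_sign
             + 0.15 * t / max(config.duration, 1e-9))
    rate = 0.05 + config.arousal_effect * (0.12 if ha else 0.02)
    gsr = tonic.copy()
    for _ in range(rng.poisson(rate * config.duration)):
        gsr += _phasic_kernel(t, rng.uniform(0, config.duration),
                              rng.exponential(0.3))
    gsr += 0.01 * config.noise_sd * rng.standard_normal(n)
    signal[idx["GSR"]] = gsr

    signal[idx["TMP"]] = (plan.tmp_base[si]
                          + rng.uniform(-0.2, 0.2) * t / max(config.duration, 1e-9)
                          + 0.005 * config.noise_sd * rng.standard_normal(n))

    # blood volume pulse at an emotion- and subject-dependent heart rate
    hr = plan.hr_base[si] + 8.0 * config.arousal_effect * a_sign
    f_inst = hr / 60.0 * (1 + 0.04 * config.noise_sd * _smooth_noise(rng, n, fs))
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    signal[idx["BVP"]] = (np.sin(phase)
                          + 0.05 * config.noise_sd * rng.standard_normal(n))

    f_r = plan.rsp_rate[si] + 0.02 * config.arousal_effect * a_sign
    signal[idx["RSP"]] = (np.sin(2 * np.pi * f_r * t + rng.uniform(0, 2 * np.pi))
                          + 0.05 * config.noise_sd * rng.standard_normal(n))

    emg_sd = 0.5 * max(config.noise_sd, 1e-12) * (1 + 0.4 * config.arousal_effect * max(a_sign, 0))
    signal[idx["EMG1"]] = emg_sd * rng.standard_normal(n)
    signal[idx["EMG2"]] = emg_sd * rng.standard_normal(n)

    heog = 0.3 * config.noise_sd * rng.standard_normal(n)
    veog = 0.3 * config.noise_sd * rng.standard_normal(n)
    for _ in range(rng.poisson(0.25 * config.duration)):
        c = rng.uniform(0, config.duration)
        veog += 3.0 * np.exp(-0.5 * ((t - c) / 0.15) ** 2)
    signal[idx["hEOG"]] = heog
    signal[idx["vEOG"]] = veog

    val, aro = plan.ratings[(subject, trial)]
    return Recording(subject_id=subject, trial_id=trial, sampling_rate=fs,
                     channels=ALL_CHANNELS, signal=signal,
                     valence=val, arousal=aro)


def generate_dataset(config: SynthConfig) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all recordings plus the planted ground-truth table.

    The same ``config`` (including seed) reproduces the dataset
    bit-identically; ``ground_truth(config)`` returns the same table
    without synthesizing any signal.
    """
    plan = _make_plan(config)
    truth = ground_truth(config)
    sig_ss = np.random.SeedSequence([config.seed, 0x516])
    children = sig_ss.spawn(len(plan.subjects) * len(plan.trials))
    recs = []
    k = 0
    for si, s in enumerate(plan.subjects):
        for t in plan.trials:
            rng = np.random.default_rng(children[k])
            k += 1
            recs.append(_generate_trial(rng, config, plan, si, s, t))
    return recs, truth
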