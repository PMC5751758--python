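"""Recordings, emotion-quadrant labels and sliding-window segmentation.

A trial is one subject watching one one-minute stimulus while 40
physiological channels are recorded, together with self-rated valence and
arousal on a 1-9 scale. Ratings are mapped onto the four quadrants of the
valence-arousal plane:

    EQ1 = high valence, high arousal     EQ2 = high valence, low arousal
    EQ3 = low valence,  low arousal      EQ4 = low valence,  high arousal

"High" means a rating strictly greater than 5; ties at 5 go to the low
side. Feature extraction operates on 4-second windows advanced in
2-second hops, so a 60 s trial yields 29 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import ALL_CHANNELS

EMOTIONS: tuple[str, ...] = ("EQ1", "EQ2", "EQ3", "EQ4")


class DomainError(ValueError):
    """Input violates a documented precondition."""


class FormatError(ValueError):
    """A file or table does not match the expected layout."""


@dataclass(frozen=True)
class Window:
    """Sliding analysis window: half-open [start, start+length) seconds."""

    length: float = 4.0
    hop: float = 2.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.hop <= 0:
            raise DomainError("window length and hop must be positive")

    def count(self, duration: float) -> int:
        """Number of full windows inside a trial of the given duration."""
        if duration < self.length:
            return 0
        return int(np.floor((duration - self.length) / self.hop)) + 1


@dataclass
class Recording:
    """One subject-trial of multichannel physiological signal.

    ``signal`` is channels x time, rows ordered as ``channels``; values
    are in channel-native units. Ratings live on the 1-9 scale.
    """

    subject_id: str
    trial_id: str
    sampling_rate: float
    channels: tuple[str, ...]
    signal: np.ndarray
    valence: float
    arousal: float
    emotion: str = field(init=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise DomainError("sampling_rate must be > 0")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise FormatError(
                f"signal has {self.signal.shape[0] if self.signal.ndim == 2 else '?'} "
                f"rows for {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite values")
        self.emotion = map_quadrant(self.valence, self.arousal)

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.signal[self.channels.index(label)]
        except ValueError:
            raise FormatError(f"channel {label!r} not present") from None

    def has_canonical_channels(self) -> bool:
        return all(c in self.channels for c in ALL_CHANNELS)


def map_quadrant(valence: float, arousal: float) -> str:
    """Map (valence, arousal) self-ratings to an emotion quadrant.

    Strict ">5" defines the high side of each dimension; a rating of
    exactly 5 counts as low. Total and single-valued on [1, 9]^2.
    """
    for name, r in (("valence", valence), ("arousal", arousal)):
        if not (1.0 <= r <= 9.0):
            raise DomainError(f"{name} rating {r} outside [1, 9]")
    hv = valence > 5.0
    ha = arousal > 5.0
    if hv and ha:
        return "EQ1"
    if hv:
        return "EQ2"
    if not ha:
        return "EQ3"
    return "EQ4"


def segment(recording: Recording, window: Window = Window(),
            max_duration: float | None = 60.0) -> list[np.ndarray]:
    """Cut a recording into sliding-window signal slices.

    Returns ``floor((duration - length)/hop) + 1`` slices of
    ``length * sampling_rate`` columns each. Trials longer than
    ``max_duration`` are truncated to it; trials shorter than one window
    raise :class:`DomainError`.
    """
    fs = recording.sampling_rate
    duration = recording.duration
    if max_duration is not None and duration > max_duration:
        duration = max_duration
    if duration < window.length:
        raise DomainError(
            f"trial duration {duration:.3f}s shorter than window {window.length}s"
        )
    n = window.count(duration)
    wlen = int(round(window.length * fs))
    hop = window.hop * fs
    out = []
    for i in range(n):
        start = int(round(i * hop))
        out.append(recording.signal[:, start:start + wlen])
    return out


def window_starts(duration: float, window: Window = Window()) -> np.ndarray:
    """Start times (seconds) of each full window inside the duration."""
    n = window.count(duration)
    return np.arange(n) * window.hop
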