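"""Canonical registry of the 742 physiological features.

Feature indices are 1-based and grouped into nine blocks:

    1-448    EEG time/frequency (14 types x 32 channels)
    449-504  EEG hemispheric asymmetry (4 bands x 14 pairs)
    505-600  EEG nonlinear (3 types x 32 channels)
    601-608  EOG (4 types x 2 channels)
    609-642  EMG (17 types x 2 channels)
    643-646  skin temperature (4 types)
    647-666  blood volume pulse / heart-rate variability (20 types)
    667-721  respiration (55 types)
    722-742  skin conductance (21 types)

Within a multi-channel block the layout is channel-major (all types of
channel 1, then channel 2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ..channels import ASYMMETRY_PAIRS, EEG_CHANNELS

EEG_BANDS: tuple[tuple[str, float, float], ...] = (
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 15.0),
    ("beta", 16.0, 31.0),
    ("gamma", 32.0, 45.0),
)

EEG_TF_TYPES = (
    "Mean", "Var", "P2P", "Skewness", "Kurtosis",
    "PSD-theta", "PSD-alpha", "PSD-beta", "PSD-gamma",
    "Beta/Theta", "Beta/Alpha",
    "Hjorth-Activity", "Hjorth-Mobility", "Hjorth-Complexity",
)
EEG_NONLINEAR_TYPES = ("SpectralEntropy", "ShannonEntropy", "C0")
EOG_TYPES = ("Mean", "Var", "P2P", "Energy")

_DIFF7 = ("Mean", "Median", "Min", "Var", "Max", "MinRatio", "MaxRatio")
EMG_TYPES = (
    ("Mean", "Var", "TotalPower")
    + tuple(f"1Diff-{t}" for t in _DIFF7)
    + tuple(f"2Diff-{t}" for t in _DIFF7)
)
TMP_TYPES = ("Mean", "1Diff-Mean", "Power-0-0.1Hz", "Power-0.1-0.2Hz")
BVP_TYPES = (
    "Hr-Mean", "Hr-Var", "Hr-Range",
    "Hrv-Mean", "Hrv-Var", "Hrv-Min", "Hrv-Max", "Hrv-Range", "Hrv-pNN50",
    "HrvDistr-Mean", "HrvDistr-Median", "HrvDistr-Var",
    "HrvDistr-Min", "HrvDistr-Max", "HrvDistr-Range", "HrvDistr-Triind",
    "Hrv-PSD-0-0.2Hz", "Hrv-PSD-0.2-0.4Hz", "Hrv-PSD-0.4-0.6Hz", "Hrv-PSD-0.6-0.8Hz",
)

_RSP_RAW = ("Mean", "Var", "Range", "MaxRatio")
_RSP_DIFF5 = ("Mean", "Median", "Var", "Range", "MaxRatio")
_RSP_DIFF7 = ("Mean", "Median", "Var", "Min", "Max", "Range", "MaxRatio")
RSP_TYPES = (
    _RSP_RAW
    + tuple(f"1Diff-{t}" for t in _RSP_DIFF5)
    + tuple(f"2Diff-{t}" for t in _RSP_DIFF5)
    + tuple(f"RSPPulse-{t}" for t in _RSP_RAW)
    + tuple(f"RSPPulse-1Diff-{t}" for t in _RSP_DIFF7)
    + tuple(f"RSPPulse-2Diff-{t}" for t in _RSP_DIFF7)
    + tuple(f"RSPAmpl-{t}" for t in _RSP_RAW)
    + tuple(f"RSPAmpl-1Diff-{t}" for t in _RSP_DIFF7)
    + tuple(f"RSPAmpl-2Diff-{t}" for t in _RSP_DIFF7)
    + ("PSD-0-0.1Hz", "PSD-0.1-0.2Hz", "PSD-0.2-0.3Hz", "PSD-0.3-0.4Hz",
       "PSD-Ratio-0-0.25/0.25-0.45")
)
_GSR_DIFF7 = ("Mean", "Median", "Var", "Min", "Max", "MinRatio", "MaxRatio")
GSR_TYPES = (
    ("RisingTime", "DecayTime",
     "Sc-Mean", "Sc-Median", "Sc-Var", "Sc-MinRatio", "Sc-MaxRatio")
    + tuple(f"Sc-1Diff-{t}" for t in _GSR_DIFF7)
    + tuple(f"Sc-2Diff-{t}" for t in _GSR_DIFF7)
)

EXPECTED_BLOCKS = {
    "eeg_tf": (1, 448),
    "asym": (449, 504),
    "eeg_nonlinear": (505, 600),
    "eog": (601, 608),
    "emg": (609, 642),
    "tmp": (643, 646),
    "bvp": (647, 666),
    "rsp": (667, 721),
    "gsr": (722, 742),
}


@dataclass(frozen=True)
class FeatureRegistry:
    """Names, channels and block membership for all 742 features."""

    names: tuple[str, ...]
    channels: tuple[str, ...]
    blocks: dict[str, tuple[int, int]]   # block -> (first, last), 1-based inclusive

    def __len__(self) -> int:
        return len(self.names)

    def block_indices(self, block: str) -> range:
        """0-based column indices of a block."""
        lo, hi = self.blocks[block]
        return range(lo - 1, hi)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        block_of = []
        for i in range(1, len(self.names) + 1):
            for b, (lo, hi) in self.blocks.items():
                if lo <= i <= hi:
                    block_of.append(b)
                    break
        return pd.DataFrame({
            "index": range(1, len(self.names) + 1),
            "name": self.names,
            "channel": self.channels,
            "block": block_of,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_registry() -> FeatureRegistry:
    names: list[str] = []
    chans: list[str] = []
    blocks: dict[str, tuple[int, int]] = {}

    def add_block(key: str, entries: list[tuple[str, str]]) -> None:
        start = len(names) + 1
        for name, ch in entries:
            names.append(name)
            chans.append(ch)
        blocks[key] = (start, len(names))

    add_block("eeg_tf", [(f"EEG-{ch}-{t}", ch)
                         for ch in EEG_CHANNELS for t in EEG_TF_TYPES])
    add_block("asym", [(f"Asym-{l}/{r}-{band}", f"{l}/{r}")
                       for (l, r) in ASYMMETRY_PAIRS
                       for (band, _, _) in EEG_BANDS])
    add_block("eeg_nonlinear", [(f"EEG-{ch}-{t}", ch)
                                for ch in EEG_CHANNELS
                                for t in EEG_NONLINEAR_TYPES])
    add_block("eog", [(f"EOG-{ch}-{t}", ch)
                      for ch in ("hEOG", "vEOG") for t in EOG_TYPES])
    add_block("emg", [(f"EMG-{ch}-{t}", ch)
                      for ch in ("EMG1", "EMG2") for t in EMG_TYPES])
    add_block("tmp", [(f"TMP-{t}", "TMP") for t in TMP_TYPES])
    add_block("bvp", [(f"BVP-{t}", "BVP") for t in BVP_TYPES])
    add_block("rsp", [(f"RSP-{t}", "RSP") for t in RSP_TYPES])
    add_block("gsr", [(f"GSR-{t}", "GSR") for t in GSR_TYPES])

    if blocks != EXPECTED_BLOCKS:
        raise AssertionError(f"feature block layout mismatch: {blocks}")
    if len(names) != 742:
        raise AssertionError(f"expected 742 features, built {len(names)}")
    return FeatureRegistry(tuple(names), tuple(chans), blocks)


REGISTRY = build_registry()
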