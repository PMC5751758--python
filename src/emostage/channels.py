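"""Canonical channel montage and alias handling.

The expected recording layout is 32 EEG electrodes placed per the
international 10-20 system plus eight peripheral channels (skin
conductance, skin temperature, blood volume pulse, respiration, two EMG
and two EOG leads), 40 channels in total.
"""

from __future__ import annotations

# 10-20 montage order used throughout the package (left block, then right).
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

PERIPHERAL_CHANNELS: tuple[str, ...] = (
    "GSR", "TMP", "BVP", "RSP", "EMG1", "EMG2", "hEOG", "vEOG",
)

ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + PERIPHERAL_CHANNELS

# Symmetric left/right electrode pairs used for hemispheric asymmetry.
# Differences are taken right minus left.
ASYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("T7", "T8"), ("C3", "C4"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
)

# Dialect labels seen in common export tools, mapped to canonical names.
CHANNEL_ALIASES: dict[str, str] = {
    "GSR1": "GSR", "SC": "GSR", "EDA": "GSR",
    "TEMP": "TMP", "TEMPERATURE": "TMP", "SKT": "TMP",
    "PLET": "BVP", "PLETH": "BVP", "PPG": "BVP", "PLETHYSMOGRAPH": "BVP",
    "RESP": "RSP", "RESPIRATION": "RSP",
    "ZEMG": "EMG1", "EMG_Z": "EMG1", "TEMG": "EMG2", "EMG_T": "EMG2",
    "HEOG": "hEOG", "VEOG": "vEOG", "EOG1": "hEOG", "EOG2": "vEOG",
}

# Coarse scalp regions (used by the synthetic generator's subject signatures).
FRONTAL = ("Fp1", "AF3", "F3", "F7", "Fp2", "AF4", "F4", "F8", "Fz")
CENTRAL = ("FC5", "FC1", "C3", "T7", "FC6", "FC2", "C4", "T8", "Cz")
POSTERIOR = (
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "CP6", "CP2", "P4", "P8", "PO4", "O2",
)


def canonical_label(label: str) -> str:
    """Map a dialect channel label to its canonical name.

    Labels already canonical pass through; unknown labels are returned
    unchanged (callers decide whether that is an error).
    """
    stripped = label.strip()
    if stripped in ALL_CHANNELS:
        return stripped
    return CHANNEL_ALIASES.get(stripped.upper(), stripped)


def channel_index(label: str) -> int:
    return ALL_CHANNELS.index(label)
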