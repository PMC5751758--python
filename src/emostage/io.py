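"""Reading and writing recordings, metadata tables and feature matrices.

Two signal formats are supported: European Data Format (EDF, read via
mne) and a plain TSV layout with one row per channel (first column the
channel label) preceded by a ``# sampling_rate_hz:`` comment line. Trial
metadata travels in a TSV table with columns subject_id, trial_id,
valence, arousal, path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ALL_CHANNELS, canonical_label
from .features.extract import TrialFeatureMatrix, WindowDataset
from .features.registry import REGISTRY
from .recording import FormatError, Recording

METADATA_COLUMNS = ("subject_id", "trial_id", "valence", "arousal", "path")


def _order_channels(labels: list[str], data: np.ndarray) -> np.ndarray:
    canon = [canonical_label(l) for l in labels]
    rows = []
    for ch in ALL_CHANNELS:
        if ch not in canon:
            raise FormatError(f"channel {ch!r} missing from file")
        rows.append(data[canon.index(ch)])
    return np.vstack(rows)


def read_recording(path, *, subject_id: str, trial_id: str,
                   valence: float, arousal: float) -> Recording:
    """Read one trial's signals from an EDF or TSV file.

    Channel labels are mapped through the alias table and reordered into
    the canonical 40-channel layout; a missing canonical channel raises
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        labels, fs, data = _read_edf(path)
    else:
        labels, fs, data = _read_signal_tsv(path)
    signal = _order_channels(labels, data)
    return Recording(subject_id=subject_id, trial_id=trial_id,
                     sampling_rate=fs, channels=ALL_CHANNELS,
                     signal=signal, valence=valence, arousal=arousal)


def _read_edf(path: Path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    return list(raw.ch_names), fs, raw.get_data()


def _read_signal_tsv(path: Path):
    fs = None
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "sampling_rate_hz" in line:
                    fs = float(line.split(":", 1)[1])
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    if fs is None:
        raise FormatError(f"{path}: missing '# sampling_rate_hz:' header")
    if not rows:
        raise FormatError(f"{path}: no channel rows")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: channel rows have differing lengths")
    return labels, fs, np.vstack(rows)


def write_recording_tsv(recording: Recording, path, fmt: str = "%.6g") -> None:
    """Write a recording in the one-row-per-channel TSV layout."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {recording.sampling_rate}\n")
        for label, row in zip(recording.channels, recording.signal):
            fh.write(label + "\t" + "\t".join(fmt % v for v in row) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the trial metadata table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata table missing columns: {sorted(missing)}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_dataset(metadata_path) -> list[Recording]:
    """Load every trial listed in a metadata table."""
    meta = read_metadata(metadata_path)
    base = Path(metadata_path).parent
    recs = []
    for row in meta.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        recs.append(read_recording(p, subject_id=str(row.subject_id),
                                   trial_id=str(row.trial_id),
                                   valence=float(row.valence),
                                   arousal=float(row.arousal)))
    return recs


def write_features(matrix: TrialFeatureMatrix, path) -> None:
    """Write one trial's window x 742 feature matrix as TSV."""
    df = pd.DataFrame(matrix.values, columns=list(REGISTRY.names))
    df.insert(0, "subject_id", matrix.subject_id)
    df.insert(1, "trial_id", matrix.trial_id)
    df.insert(2, "emotion", matrix.emotion)
    df.insert(3, "window", range(matrix.n_windows))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_features(path) -> TrialFeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str})
    names = list(REGISTRY.names)
    if not set(names).issubset(df.columns):
        raise FormatError("feature TSV does not carry the canonical 742 columns")
    values = df[names].to_numpy(dtype=float)
    return TrialFeatureMatrix(
        subject_id=df["subject_id"].iloc[0], trial_id=df["trial_id"].iloc[0],
        emotion=df["emotion"].iloc[0], valence=np.nan, arousal=np.nan,
        values=values, missing=np.zeros_like(values, dtype=bool))


def write_window_dataset(ds: WindowDataset, path) -> None:
    """Write a whole-study window dataset (metadata + features) as TSV."""
    df = pd.concat(
        [ds.meta.reset_index(drop=True),
         pd.DataFrame(ds.X, columns=list(ds.registry.names))], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
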