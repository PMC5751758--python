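"""Per-channel feature computations for one analysis window.

All statistical moments use the population convention (divide by n).
Band powers are the mean of the mean-removed periodogram over bins whose
center frequency lies in the half-open band [lo, hi); a band containing
no bin has power 0. Degenerate inputs (constant signals, empty derived
series) follow the conventions documented in docs/methods.md: undefined
ratios and moments are 0 rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .registry import EEG_BANDS

# --------------------------------------------------------------------------
# primitives


def _var(x: np.ndarray) -> float:
    return float(np.var(x)) if x.size else 0.0


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else 0.0


def _median(x: np.ndarray) -> float:
    return float(np.median(x)) if x.size else 0.0


def _min(x: np.ndarray) -> float:
    return float(np.min(x)) if x.size else 0.0


def _max(x: np.ndarray) -> float:
    return float(np.max(x)) if x.size else 0.0


def _range(x: np.ndarray) -> float:
    return float(np.ptp(x)) if x.size else 0.0


def _is_constant(x: np.ndarray) -> bool:
    return x.size == 0 or np.ptp(x) == 0


def skewness(x: np.ndarray) -> float:
    """Population skewness; 0 for a zero-variance signal."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    s = np.std(x)
    return float(np.mean(((x - np.mean(x)) / s) ** 3))


def kurtosis_excess(x: np.ndarray) -> float:
    """Population excess kurtosis; 0 for a zero-variance signal."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    s = np.std(x)
    return float(np.mean(((x - np.mean(x)) / s) ** 4) - 3.0)


def periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed one-sided periodogram (rectangular window, FFT based).

    Equivalent to ``scipy.signal.periodogram(x, fs, detrend="constant")``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.fft.rfft(x - x.mean())
    pxx = (np.abs(spec) ** 2) / (fs * n)
    pxx[1:] *= 2.0
    if n % 2 == 0 and pxx.size > 1:
        pxx[-1] /= 2.0
    return np.fft.rfftfreq(n, 1.0 / fs), pxx


def band_power(f: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    """Mean PSD over bins with center frequency in [lo, hi)."""
    mask = (f >= lo) & (f < hi)
    if not np.any(mask):
        return 0.0
    return float(np.mean(pxx[mask]))


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x). Degenerate denominators -> 0.
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0, 0.0, 0.0
    v0 = np.var(x)
    d1 = np.diff(x)
    v1 = np.var(d1)
    mobility = float(np.sqrt(v1 / v0))
    if v1 == 0:
        return float(v0), mobility, 0.0
    d2 = np.diff(d1)
    v2 = np.var(d2)
    mob_d = np.sqrt(v2 / v1)
    return float(v0), mobility, float(mob_d / mobility)


def extrema_counts(x: np.ndarray) -> tuple[int, int]:
    """Counts of local maxima and minima via cyclic slope-sign alternation.

    Zero slopes carry the previous nonzero sign (plateaus do not split an
    extremum); the slope-sign sequence is closed cyclically so a signal
    ending mid-descent still pairs its extrema. Monotone signals have no
    extrema.
    """
    d = np.diff(np.asarray(x, dtype=float))
    signs = np.sign(d)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0, 0
    ext = np.concatenate([nz, nz[:1]])
    maxima = int(np.sum((ext[:-1] > 0) & (ext[1:] < 0)))
    minima = int(np.sum((ext[:-1] < 0) & (ext[1:] > 0)))
    return maxima, minima


def max_ratio(x: np.ndarray) -> float:
    """Local-maximum count divided by the series length."""
    if len(x) == 0:
        return 0.0
    return extrema_counts(x)[0] / len(x)


def min_ratio(x: np.ndarray) -> float:
    if len(x) == 0:
        return 0.0
    return extrema_counts(x)[1] / len(x)


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Shannon entropy of the normalized power spectrum, scaled to [0, 1].

    A pure tone approaches 0, broadband white noise approaches 1.
    """
    f, pxx = periodogram(x, fs)
    p = pxx[f > 0]
    total = p.sum()
    if total <= 0 or p.size < 2:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(p.size))


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (bits) of the amplitude histogram.

    Equal-width bins over the window's own amplitude range; a constant
    signal occupies a single bin and has entropy 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def c0_complexity(x: np.ndarray) -> float:
    """Spectral C0 complexity: share of power outside dominant components.

    FFT components of the mean-removed signal whose squared amplitude
    exceeds the mean squared amplitude form the "regular" part; C0 is the
    residual power divided by the total power. 0 for a pure tone, near 1
    for a flat spectrum.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or _is_constant(x):
        return 0.0
    spec = np.fft.rfft(x - np.mean(x))
    power = np.abs(spec) ** 2
    total = power.sum()
    if total <= 0:
        return 0.0
    keep = power > power.mean()
    return float(power[~keep].sum() / total)


def _diff_stats(values: np.ndarray, fields: tuple[str, ...]) -> list[float]:
    out = []
    for fld in fields:
        if fld == "Mean":
            out.append(_mean(values))
        elif fld == "Median":
            out.append(_median(values))
        elif fld == "Var":
            out.append(_var(values))
        elif fld == "Min":
            out.append(_min(values))
        elif fld == "Max":
            out.append(_max(values))
        elif fld == "Range":
            out.append(_range(values))
        elif fld == "MinRatio":
            out.append(min_ratio(values))
        elif fld == "MaxRatio":
            out.append(max_ratio(values))
        else:  # pragma: no cover - registry and blocks are built together
            raise KeyError(fld)
    return out


# --------------------------------------------------------------------------
# EEG


def _eeg_channel(x: np.ndarray, fs: float):
    """Shared per-channel EEG computation (one FFT per channel)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.fft.rfft(x - x.mean())
    power = np.abs(spec) ** 2
    pxx = power / (fs * n)
    pxx[1:] *= 2.0
    if n % 2 == 0 and pxx.size > 1:
        pxx[-1] /= 2.0
    f = np.fft.rfftfreq(n, 1.0 / fs)
    bands = np.array([band_power(f, pxx, lo, hi) for _, lo, hi in EEG_BANDS])
    theta, alpha, beta, _gamma = bands
    activity, mobility, complexity = hjorth_parameters(x)
    tf = [
        _mean(x), _var(x), _range(x), skewness(x), kurtosis_excess(x),
        bands[0], bands[1], bands[2], bands[3],
        beta / theta if theta > 0 else 0.0,
        beta / alpha if alpha > 0 else 0.0,
        activity, mobility, complexity,
    ]
    p = pxx[f > 0]
    total = p.sum()
    if total > 0 and p.size >= 2:
        q = p / total
        nzq = q[q > 0]
        spec_ent = float(-(nzq * np.log2(nzq)).sum() / np.log2(q.size))
    else:
        spec_ent = 0.0
    # C0 from the same spectrum: residual power of below-mean components
    ptot = power.sum()
    if ptot > 0:
        keep = power > power.mean()
        c0 = float(power[~keep].sum() / ptot)
    else:
        c0 = 0.0
    nonlinear = [spec_ent, shannon_entropy(x), c0]
    return np.array(tf), bands, np.array(nonlinear)


def eeg_time_freq(x: np.ndarray, fs: float) -> np.ndarray:
    """14 time/frequency features of one EEG channel window.

    Order: mean, variance, peak-to-peak, skewness, kurtosis; mean PSD in
    theta/alpha/beta/gamma; beta/theta and beta/alpha power ratios;
    Hjorth activity, mobility, complexity.
    """
    return _eeg_channel(x, fs)[0]


def eeg_band_psd(x: np.ndarray, fs: float) -> np.ndarray:
    """Mean PSD in the four canonical EEG bands (theta, alpha, beta, gamma)."""
    return _eeg_channel(x, fs)[1]


def eeg_nonlinear(x: np.ndarray, fs: float) -> np.ndarray:
    """Spectral entropy, Shannon entropy and C0 complexity of one channel."""
    return _eeg_channel(x, fs)[2]


def hemispheric_asymmetry(left_psd: np.ndarray, right_psd: np.ndarray) -> np.ndarray:
    """Right-minus-left mean band PSD for one symmetric channel pair."""
    left_psd = np.asarray(left_psd, dtype=float)
    right_psd = np.asarray(right_psd, dtype=float)
    if left_psd.shape != (4,) or right_psd.shape != (4,):
        raise ValueError("band PSD vectors must have 4 entries (theta..gamma)")
    return right_psd - left_psd


# --------------------------------------------------------------------------
# peripheral channels


def eog_features(x: np.ndarray) -> np.ndarray:
    """Mean, variance, peak-to-peak amplitude and energy (mean square)."""
    x = np.asarray(x, dtype=float)
    return np.array([_mean(x), _var(x), _range(x), _mean(x ** 2)])


def emg_features(x: np.ndarray, fs: float) -> np.ndarray:
    """17 EMG features: raw stats, total spectral power, 1st/2nd difference stats."""
    x = np.asarray(x, dtype=float)
    f, pxx = periodogram(x, fs)
    total_power = float(np.mean(pxx[f > 0])) if np.any(f > 0) else 0.0
    d1 = np.diff(x)
    d2 = np.diff(d1)
    fields = ("Mean", "Median", "Min", "Var", "Max", "MinRatio", "MaxRatio")
    return np.array(
        [_mean(x), _var(x), total_power]
        + _diff_stats(d1, fields)
        + _diff_stats(d2, fields)
    )


def tmp_features(x: np.ndarray, fs: float) -> np.ndarray:
    """Skin-temperature mean, first-difference mean and two slow band powers."""
    x = np.asarray(x, dtype=float)
    f, pxx = periodogram(x, fs)
    return np.array([
        _mean(x), _mean(np.diff(x)),
        band_power(f, pxx, 0.0, 0.1), band_power(f, pxx, 0.1, 0.2),
    ])


def detect_beats(x: np.ndarray, fs: float) -> np.ndarray:
    """Pulse peak sample indices from a BVP window.

    The pulse wave is band-passed to 0.5-8 Hz and local maxima are kept
    with a minimum inter-peak distance of 0.35 s and a prominence of 30%
    of the filtered signal's standard deviation.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 32 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    nyq = fs / 2.0
    hi = min(8.0, 0.99 * nyq)
    sos = sps.butter(3, [0.5, hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    sd = np.std(filt)
    if sd == 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(filt, distance=max(1, int(0.35 * fs)),
                              prominence=0.3 * sd)
    return peaks


def nn_intervals_ms(x: np.ndarray, fs: float) -> np.ndarray:
    """Inter-beat (NN) intervals in milliseconds from a BVP window."""
    peaks = detect_beats(x, fs)
    if peaks.size < 2:
        return np.array([])
    return np.diff(peaks) / fs * 1000.0


def pnn50(nn_ms: np.ndarray) -> float:
    """Fraction of adjacent NN-interval pairs differing by more than 50 ms."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if nn_ms.size < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(nn_ms)) > 50.0))


def triangular_index(nn_ms: np.ndarray, bin_width_ms: float = 1000.0 / 128.0) -> float:
    """Total NN count divided by the height of the NN histogram mode.

    The conventional HRV bin width of 1/128 s is the default; all
    intervals equal puts the whole mass in one bin and gives 1.
    """
    nn_ms = np.asarray(nn_ms, dtype=float)
    if nn_ms.size == 0:
        return 0.0
    counts = _nn_histogram(nn_ms, bin_width_ms)
    return float(nn_ms.size / counts.max())


def _nn_histogram(nn_ms: np.ndarray, bin_width_ms: float = 1000.0 / 128.0) -> np.ndarray:
    lo = np.floor(nn_ms.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil((nn_ms.max() + 1e-9) / bin_width_ms) * bin_width_ms
    n_bins = max(1, int(round((hi - lo) / bin_width_ms)))
    counts, _ = np.histogram(nn_ms, bins=n_bins, range=(lo, hi))
    return counts


def nn_series_features(nn_ms: np.ndarray) -> np.ndarray:
    """The 20 heart-rate / HRV features from an NN-interval series (ms)."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if nn_ms.size == 0:
        return np.zeros(20)
    hr = 60000.0 / nn_ms                       # instantaneous bpm
    counts = _nn_histogram(nn_ms).astype(float)
    if nn_ms.size >= 2:
        fs_nn = 1000.0 / np.mean(nn_ms)        # beats per second
        f, pxx = periodogram(nn_ms, fs_nn)
        psd = [band_power(f, pxx, lo, lo + 0.2) for lo in (0.0, 0.2, 0.4, 0.6)]
    else:
        psd = [0.0, 0.0, 0.0, 0.0]
    return np.array([
        _mean(hr), _var(hr), _range(hr),
        _mean(nn_ms), _var(nn_ms), _min(nn_ms), _max(nn_ms), _range(nn_ms),
        pnn50(nn_ms),
        _mean(counts), _median(counts), _var(counts),
        _min(counts), _max(counts), _range(counts),
        triangular_index(nn_ms),
        *psd,
    ])


def bvp_features(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """20 BVP features and their missing mask.

    Fewer than two detectable beats leaves no NN interval; the whole
    block is then flagged missing for downstream imputation.
    """
    nn = nn_intervals_ms(x, fs)
    if nn.size == 0:
        return np.zeros(20), np.ones(20, dtype=bool)
    return nn_series_features(nn), np.zeros(20, dtype=bool)


def breath_cycles(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Breath peak times (s) and amplitudes via zero-crossing + peak pairing.

    The mean-removed signal is cut at upward zero crossings; each cycle
    contributes one peak (its maximum) and an amplitude (max - min).
    """
    x = np.asarray(x, dtype=float) - _mean(np.asarray(x, dtype=float))
    up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0] + 1
    if up.size < 2:
        return np.array([]), np.array([])
    times, amps = [], []
    for a, b in zip(up[:-1], up[1:]):
        seg = x[a:b]
        if seg.size == 0:
            continue
        peak = a + int(np.argmax(seg))
        times.append(peak / fs)
        amps.append(float(seg.max() - seg.min()))
    return np.array(times), np.array(amps)


def rsp_features(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """55 respiration features and their missing mask.

    Raw-signal and spectral features are always computed; the breath
    interval ("pulse") and breath amplitude sub-series need at least two
    detected cycles, otherwise their entries are flagged missing.
    """
    x = np.asarray(x, dtype=float)
    values = np.zeros(55)
    missing = np.zeros(55, dtype=bool)
    d1, d2 = np.diff(x), np.diff(x, n=2)
    raw = ("Mean", "Var", "Range", "MaxRatio")
    diff5 = ("Mean", "Median", "Var", "Range", "MaxRatio")
    diff7 = ("Mean", "Median", "Var", "Min", "Max", "Range", "MaxRatio")

    values[0:4] = _diff_stats(x, raw)
    values[4:9] = _diff_stats(d1, diff5)
    values[9:14] = _diff_stats(d2, diff5)

    peak_times, amps = breath_cycles(x, fs)
    intervals = np.diff(peak_times) if peak_times.size >= 2 else np.array([])

    def sub_series(series: np.ndarray, start: int) -> int:
        stop = start + 4 + 7 + 7
        if series.size < 2:
            missing[start:stop] = True
            return stop
        s1, s2 = np.diff(series), np.diff(series, n=2)
        values[start:start + 4] = _diff_stats(series, raw)
        values[start + 4:start + 11] = _diff_stats(s1, diff7)
        values[start + 11:start + 18] = _diff_stats(s2, diff7)
        return stop

    pos = sub_series(intervals, 14)
    pos = sub_series(amps, pos)

    f, pxx = periodogram(x, fs)
    values[pos:pos + 4] = [band_power(f, pxx, lo, lo + 0.1)
                           for lo in (0.0, 0.1, 0.2, 0.3)]
    num = band_power(f, pxx, 0.0, 0.25)
    den = band_power(f, pxx, 0.25, 0.45)
    values[pos + 4] = num / den if den > 0 else 0.0
    return values, missing


def gsr_features(x: np.ndarray, fs: float) -> np.ndarray:
    """21 skin-conductance features (rising/decay times, level and diff stats)."""
    x = np.asarray(x, dtype=float)
    d1, d2 = np.diff(x), np.diff(x, n=2)
    fields = ("Mean", "Median", "Var", "Min", "Max", "MinRatio", "MaxRatio")
    return np.array(
        [float(np.sum(d1 > 0)) / fs, float(np.sum(d1 < 0)) / fs,
         _mean(x), _median(x), _var(x), min_ratio(x), max_ratio(x)]
        + _diff_stats(d1, fields)
        + _diff_stats(d2, fields)
    )
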