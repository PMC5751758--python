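"""Independent brute-force oracles for feature and score definitions.

Deliberately naive implementations (explicit loops, O(n^2) DFT) written
straight from the definitions; they never import the package's
computation paths and serve as the reference in equivalence tests.
"""

from __future__ import annotations

import cmath
import math


def mean(xs):
    return sum(xs) / len(xs)


def var(xs):
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def median(xs):
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def ptp(xs):
    return max(xs) - min(xs)


def skewness(xs):
    s = math.sqrt(var(xs))
    if s == 0:
        return 0.0
    m = mean(xs)
    return mean([((x - m) / s) ** 3 for x in xs])


def kurtosis_excess(xs):
    s = math.sqrt(var(xs))
    if s == 0:
        return 0.0
    m = mean(xs)
    return mean([((x - m) / s) ** 4 for x in xs]) - 3.0


def diff(xs):
    return [b - a for a, b in zip(xs[:-1], xs[1:])]


def extrema_counts(xs):
    """Cyclic slope-sign alternation count of maxima and minima."""
    signs = [1 if d > 0 else -1 for d in diff(xs) if d != 0]
    if len(signs) < 2:
        return 0, 0
    signs = signs + signs[:1]
    maxima = sum(1 for a, b in zip(signs[:-1], signs[1:]) if a > 0 > b)
    minima = sum(1 for a, b in zip(signs[:-1], signs[1:]) if a < 0 < b)
    return maxima, minima


def periodogram(xs, fs):
    """One-sided mean-removed periodogram via an explicit O(n^2) DFT."""
    n = len(xs)
    m = mean(xs)
    centered = [x - m for x in xs]
    freqs, pxx = [], []
    for k in range(n // 2 + 1):
        coeff = sum(centered[j] * cmath.exp(-2j * math.pi * k * j / n)
                    for j in range(n))
        p = abs(coeff) ** 2 / (fs * n)
        if k not in (0, n / 2):
            p *= 2
        freqs.append(k * fs / n)
        pxx.append(p)
    return freqs, pxx


def band_power(xs, fs, lo, hi):
    freqs, pxx = periodogram(xs, fs)
    sel = [p for f, p in zip(freqs, pxx) if lo <= f < hi]
    return mean(sel) if sel else 0.0


def hjorth(xs):
    v0 = var(xs)
    if v0 == 0:
        return 0.0, 0.0, 0.0
    d1 = diff(xs)
    v1 = var(d1)
    mobility = math.sqrt(v1 / v0)
    if v1 == 0:
        return v0, mobility, 0.0
    v2 = var(diff(d1))
    return v0, mobility, math.sqrt(v2 / v1) / mobility


def shannon_entropy(xs, n_bins=16):
    lo, hi = min(xs), max(xs)
    if hi == lo:
        return 0.0
    counts = [0] * n_bins
    for x in xs:
        b = min(int((x - lo) / (hi - lo) * n_bins), n_bins - 1)
        counts[b] += 1
    n = len(xs)
    return -sum(c / n * math.log2(c / n) for c in counts if c)


def spectral_entropy(xs, fs):
    freqs, pxx = periodogram(xs, fs)
    p = [v for f, v in zip(freqs, pxx) if f > 0]
    total = sum(p)
    if total <= 0 or len(p) < 2:
        return 0.0
    q = [v / total for v in p]
    return -sum(v * math.log2(v) for v in q if v > 0) / math.log2(len(q))


def c0_complexity(xs):
    """Residual power share after keeping above-mean spectral components."""
    n = len(xs)
    m = mean(xs)
    centered = [x - m for x in xs]
    powers = []
    for k in range(n // 2 + 1):
        coeff = sum(centered[j] * cmath.exp(-2j * math.pi * k * j / n)
                    for j in range(n))
        powers.append(abs(coeff) ** 2)
    total = sum(powers)
    if total <= 0:
        return 0.0
    thresh = mean(powers)
    residual = sum(p for p in powers if p <= thresh)
    return residual / total


def pnn50(nn_ms):
    diffs = [abs(d) for d in diff(nn_ms)]
    if not diffs:
        return 0.0
    return sum(1 for d in diffs if d > 50) / len(diffs)


def fcs(values_a, values_b):
    num = (mean(values_a) - mean(values_b)) ** 2
    den = var(values_a) + var(values_b)
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return num / den


def fcs_multiclass(columns, labels):
    """Mean one-vs-rest Fisher score per feature column."""
    classes = sorted(set(labels))
    out = []
    for col in columns:
        total = 0.0
        for c in classes:
            a = [v for v, l in zip(col, labels) if l == c]
            b = [v for v, l in zip(col, labels) if l != c]
            total += fcs(a, b)
        out.append(total / len(classes))
    return out
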