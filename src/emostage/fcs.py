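"""Fisher Criterion Score (FCS) feature ranking.

For a two-class labeling the score of feature *l* is

    F_l = (m1 - m2)^2 / (s1^2 + s2^2)

with class means m and population standard deviations s. A feature that
separates two non-identical class means with zero within-class variance
is a perfect separator and scores +inf; identical class means with zero
variance score 0. For more than two classes the score is the mean of the
one-vs-rest two-class scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import DomainError


def fcs_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Fisher score of a single feature for a two-class labeling."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DomainError(f"need exactly 2 classes, got {classes.size}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    return float(_fcs_columns(a[:, None], b[:, None])[0])


def _fcs_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-class FCS over feature columns."""
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0) + b.var(axis=0)
    out = np.zeros(a.shape[1])
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[~nz & (num > 0)] = np.inf
    return out


def fcs_scores(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature FCS for 2 or more classes (mean one-vs-rest beyond 2)."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if matrix.size == 0:
        raise DomainError("empty feature matrix")
    classes = np.unique(labels)
    if classes.size < 2:
        raise DomainError("feature ranking needs at least 2 classes")
    if classes.size == 2:
        return _fcs_columns(matrix[labels == classes[0]],
                            matrix[labels == classes[1]])
    scores = np.zeros(matrix.shape[1])
    for c in classes:
        scores += _fcs_columns(matrix[labels == c], matrix[labels != c])
    return scores / classes.size


@dataclass
class RankedFeatureList:
    """Feature indices (0-based columns) sorted by descending Fisher score."""

    indices: np.ndarray
    scores: np.ndarray
    label_context: str = ""

    def top(self, n: int) -> np.ndarray:
        """The 0-based indices of the n best features."""
        return self.indices[:n]

    def top_set(self, n: int) -> set[int]:
        return set(int(i) for i in self.indices[:n])

    def to_frame(self, names=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "rank": np.arange(1, self.indices.size + 1),
            "feature_index": self.indices + 1,    # 1-based, registry convention
            "score": self.scores,
        })
        if names is not None:
            df.insert(2, "name", [names[i] for i in self.indices])
        return df

    def to_tsv(self, path, names=None) -> None:
        self.to_frame(names).to_csv(path, sep="\t", index=False)


def rank_features(matrix: np.ndarray, labels: np.ndarray,
                  label_context: str = "") -> RankedFeatureList:
    """Rank all feature columns by FCS, ties broken by ascending index."""
    scores = fcs_scores(matrix, labels)
    # stable sort on ascending index, then stable sort on descending score
    order = np.arange(scores.size)
    order = order[np.argsort(-scores[order], kind="stable")]
    return RankedFeatureList(order, scores[order], label_context)
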