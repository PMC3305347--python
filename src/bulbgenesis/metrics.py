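"""Pattern-similarity and connectivity summaries.

All similarity claims of the model are phrased in terms of the Pearson
correlation between activity patterns; this module centralizes its
computation, the handling of zero-variance (undefined) pairs, block sums of
the effective connectivity, and the display ordering used for connectivity
matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedCorrelationWarning", "CorrelationReport", "pearson",
    "correlation_matrix", "mean_correlation", "quadrant_sums",
    "sort_for_display",
]


class UndefinedCorrelationWarning(UserWarning):
    """A correlation involved a zero-variance pattern and is undefined."""


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two activity patterns.

    Returns ``nan`` (with :class:`UndefinedCorrelationWarning`) if either
    vector has zero variance; downstream averages exclude such pairs.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("patterns must have equal length")
    if a.size < 2:
        raise ValueError("patterns must have length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        warnings.warn("zero-variance pattern: correlation undefined",
                      UndefinedCorrelationWarning, stacklevel=2)
        return float("nan")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix over stimuli plus its off-diagonal mean."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if len(self.labels) != m.shape[0]:
            raise ValueError("labels must match matrix size")

    @property
    def mean(self) -> float:
        """Mean correlation over unordered distinct pairs (diagonal excluded).

        Undefined (nan) pairs are excluded from the average.
        """
        iu = np.triu_indices_from(self.matrix, k=1)
        vals = self.matrix[iu]
        return float(np.nanmean(vals)) if vals.size else float("nan")

    def pair(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(csv_path)
        if json_path is not None:
            payload = {"labels": self.labels, "mean_correlation": self.mean}
            Path(json_path).write_text(json.dumps(payload, indent=2))


def correlation_matrix(patterns, labels: Sequence[str] | None = None
                       ) -> CorrelationReport:
    """Pairwise Pearson correlations of a set of patterns.

    ``patterns`` may be a ``(n_channels, n_patterns)`` array (columns are
    patterns, e.g. the mitral-activity block of a steady state), a
    ``StimulusEnsemble``, or any object with a ``matrix`` attribute holding
    stimuli as rows.
    """
    if hasattr(patterns, "matrix"):
        X = np.asarray(patterns.matrix, dtype=float).T  # channels x stimuli
        if labels is None and hasattr(patterns, "labels"):
            labels = patterns.labels
    else:
        X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two patterns")
    S = X.shape[1]
    if labels is None:
        labels = [f"s{i}" for i in range(S)]
    C = np.eye(S)
    for i in range(S):
        for j in range(i + 1, S):
            C[i, j] = C[j, i] = pearson(X[:, i], X[:, j])
    return CorrelationReport(C, list(labels))


def mean_correlation(patterns, labels: Sequence[str] | None = None) -> float:
    """Average Pearson correlation over unordered distinct pattern pairs."""
    return correlation_matrix(patterns, labels).mean


def quadrant_sums(W: np.ndarray,
                  partition: tuple[Sequence[int], Sequence[int]]) -> np.ndarray:
    """Off-diagonal block sums of the effective connectivity.

    The mitral cells are split into two disjoint groups covering all indices
    (e.g. cells dominated by one mixture component vs the other); the four
    quadrant sums of ``W`` — excluding the self-inhibition diagonal — compare
    the inhibition carried by "pure" and "mixed" granule-cell populations.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    ia, ib = (np.asarray(p, dtype=int) for p in partition)
    if np.intersect1d(ia, ib).size:
        raise ValueError("partition groups overlap")
    covered = np.sort(np.concatenate([ia, ib]))
    if not np.array_equal(covered, np.arange(W.shape[0])):
        raise ValueError("partition must cover all mitral indices")
    Woff = W - np.diag(np.diag(W))
    out = np.empty((2, 2))
    for r, rows in enumerate((ia, ib)):
        for c, cols in enumerate((ia, ib)):
            out[r, c] = Woff[np.ix_(rows, cols)].sum()
    return out


def sort_for_display(pattern_a: np.ndarray, pattern_b: np.ndarray) -> np.ndarray:
    """Permutation placing cells dominated by pattern A first, by B last.

    Cells are ordered by decreasing ``drive_A - drive_B``, so strongly
    A-driven cells come first, strongly B-driven ones last, and cells shared
    by both stimuli end up in the middle.  Ties are broken stably by index.
    Display-only; no computation depends on this ordering.
    """
    a = np.asarray(pattern_a, dtype=float).ravel()
    b = np.asarray(pattern_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("patterns must have equal length")
    score = a - b
    # stable sort on negated score -> descending with index tie-break
    return np.argsort(-score, kind="stable")
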