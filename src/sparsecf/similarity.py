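"""Pairwise user-user similarity on sparse matrices, and ISC summaries.

Similarities are computed over pairwise-complete items only: for a pair of
users, the items both have rated. Pairs with fewer than ``min_overlap``
shared items, or a zero-variance vector over the overlap (for correlation
metrics), are *undefined* and stored as NaN -- downstream neighborhood
prediction treats an undefined similarity as "no neighbor relation", never
as a similarity of zero.

The intersubject correlation (ISC) summary -- the mean and SD of the
pairwise Pearson similarities -- is the dataset-level consensus statistic:
high mean ISC means users rate alike (normed static stimuli), low mean ISC
means idiosyncratic responses (continuous affect time-series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import RatingsMatrix

__all__ = ["SimilarityMatrix", "pairwise_similarity", "isc_summary", "METRICS"]

METRICS = ("pearson", "spearman", "kendall", "cosine")


@dataclass
class SimilarityMatrix:
    """Symmetric user x user similarity with NaN for undefined pairs."""

    user_ids: list
    values: np.ndarray
    metric: str
    min_overlap: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.user_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")

    def lower_triangle(self) -> np.ndarray:
        """Defined entries of the strictly lower triangle, as a flat array."""
        idx = np.tril_indices(len(self.user_ids), k=-1)
        vals = self.values[idx]
        return vals[np.isfinite(vals)]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.user_ids, columns=self.user_ids).to_csv(
            path, index_label="user", na_rep=""
        )


def _pair_similarity(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Similarity of two complete (no-NaN) vectors; NaN when undefined."""
    if metric == "cosine":
        nx = np.linalg.norm(x)
        ny = np.linalg.norm(y)
        if nx == 0.0 or ny == 0.0:
            return np.nan
        return float(x @ y / (nx * ny))
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan
    if metric == "pearson":
        if x.size == 2:
            # two points determine the correlation exactly: +/-1
            return 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
        return float(np.corrcoef(x, y)[0, 1])
    if metric == "spearman":
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        if rx.std() == 0.0 or ry.std() == 0.0:
            return np.nan
        if rx.size == 2:
            return 1.0 if (rx[1] - rx[0]) * (ry[1] - ry[0]) > 0 else -1.0
        return float(np.corrcoef(rx, ry)[0, 1])
    if metric == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_similarity(
    matrix: RatingsMatrix, metric: str = "pearson", min_overlap: int = 2
) -> SimilarityMatrix:
    """All-pairs user similarity over pairwise-complete items.

    Parameters
    ----------
    metric
        One of ``pearson``, ``spearman`` (rank transform then Pearson),
        ``kendall`` (tau-b), or ``cosine`` (on raw, uncentered vectors).
    min_overlap
        Minimum number of co-rated items for a pair to be defined. Must be
        at least 2 for the correlation metrics.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric != "cosine" and min_overlap < 2:
        raise ValueError("min_overlap must be >= 2 for correlation metrics")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    v = matrix.values
    obs = np.isfinite(v)
    n = matrix.n_users
    sim = np.full((n, n), np.nan)
    if metric == "pearson" and obs.all() and matrix.n_items >= min_overlap:
        # dense fast path: one matrix-level correlation call
        sds = v.std(axis=1)
        ok = sds > 0
        if ok.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                full = np.corrcoef(v)
            sim[np.ix_(ok, ok)] = full[np.ix_(ok, ok)]
            sim[~ok, :] = np.nan
            sim[:, ~ok] = np.nan
        return SimilarityMatrix(list(matrix.user_ids), sim, metric, min_overlap)
    for u in range(n):
        for w in range(u, n):
            shared = obs[u] & obs[w]
            if shared.sum() < min_overlap:
                continue
            s = _pair_similarity(v[u, shared], v[w, shared], metric)
            sim[u, w] = s
            sim[w, u] = s
    return SimilarityMatrix(list(matrix.user_ids), sim, metric, min_overlap)


def isc_summary(matrix: RatingsMatrix, min_overlap: int = 2) -> tuple[float, float]:
    """Mean and SD of pairwise intersubject Pearson correlation.

    Computed over the defined entries of the strictly lower triangle of the
    Pearson similarity matrix. Raises if no pair is defined. The SD uses the
    population convention (ddof=0), so identical users give exactly (1, 0).
    """
    sim = pairwise_similarity(matrix, metric="pearson", min_overlap=min_overlap)
    vals = sim.lower_triangle()
    if vals.size == 0:
        raise ValueError("no user pair has a defined correlation")
    return float(vals.mean()), float(vals.std())
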