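"""Chronologically constrained clustering of years with a broken-stick test.

CONISS-style agglomeration: every cluster is a contiguous run of years, and
at each step the two *adjacent* clusters whose merge least increases the
total within-group sum of squares (squared Euclidean dispersion about the
cluster centroid) are joined.  The result is a dendrogram over the time
axis; the within-group dispersion at each cluster count k is the zonation
profile.

How many zones are real is decided by a broken-stick comparison: the
dispersion drop achieved by the k-th split is compared with the share of the
total dispersion that the k-th largest of T randomly sized contiguous
groups of years would claim (estimated by Monte Carlo; this converges to
the classical broken-stick expectation (1/T) * sum_{i=k..T} 1/i).  The
significant zone count is the largest k reached while every split up to k
beats its random expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _within_ss(X: np.ndarray) -> float:
    """Sum of squared Euclidean distances to the centroid."""
    if X.shape[0] <= 1:
        return 0.0
    c = X.mean(axis=0)
    return float(((X - c) ** 2).sum())


def _partition_ss(X: np.ndarray, boundaries) -> float:
    """Total within-group SS of a contiguous partition given cut indices."""
    total = 0.0
    start = 0
    for b in list(boundaries) + [X.shape[0]]:
        total += _within_ss(X[start:b])
        start = b
    return total


@dataclass
class ZonationResult:
    """Dendrogram and dispersion profile from constrained clustering."""

    years: np.ndarray
    merges: list  # (left_cluster_years, right_cluster_years, merge_increment)
    dispersion_by_k: np.ndarray  # index j -> total within-group SS at k = j+1
    boundaries_by_k: dict  # k -> sorted year values starting each cluster but the first

    def clusters(self, k: int) -> list[np.ndarray]:
        """The k contiguous year groups at level k."""
        cuts = self.boundaries_by_k[k]
        idx = np.searchsorted(self.years, cuts)
        groups = np.split(self.years, idx)
        return groups


def coniss(matrix, years=None) -> ZonationResult:
    """Constrained incremental sum-of-squares clustering of ordered years.

    Parameters
    ----------
    matrix : (T, p) array or DataFrame of year features (no missing values).
    years : optional sequence of year labels; defaults to the DataFrame
        index or 0..T-1.
    """
    if isinstance(matrix, pd.DataFrame):
        if years is None:
            years = matrix.index.to_numpy()
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if years is None:
            years = np.arange(X.shape[0])
    years = np.asarray(years)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    T = X.shape[0]
    if T < 2:
        raise ValueError("need at least two years")

    # clusters as [start, end) index ranges, kept in time order
    bounds = [(i, i + 1) for i in range(T)]
    ss = [0.0] * T
    dispersion = np.zeros(T)  # dispersion_by_k[k-1] filled as we merge
    dispersion[T - 1] = 0.0
    boundaries_by_k = {T: years[1:].tolist()}
    merges = []
    current = 0.0
    n_clusters = T
    while n_clusters > 1:
        best_i, best_inc, best_ss = -1, np.inf, 0.0
        for i in range(n_clusters - 1):
            lo = bounds[i][0]
            hi = bounds[i + 1][1]
            merged_ss = _within_ss(X[lo:hi])
            inc = merged_ss - ss[i] - ss[i + 1]
            if inc < best_inc - 1e-12:
                best_i, best_inc, best_ss = i, inc, merged_ss
        i = best_i
        left_years = years[bounds[i][0]:bounds[i][1]]
        right_years = years[bounds[i + 1][0]:bounds[i + 1][1]]
        merges.append((left_years, right_years, best_inc))
        bounds[i] = (bounds[i][0], bounds[i + 1][1])
        ss[i] = best_ss
        del bounds[i + 1], ss[i + 1]
        n_clusters -= 1
        current += best_inc
        dispersion[n_clusters - 1] = current
        boundaries_by_k[n_clusters] = [years[b[0]] for b in bounds[1:]]

    # merge costs telescope: the cumulative cost once k clusters remain equals
    # the within-group SS of that k-partition, so dispersion[k-1] is D(k)
    return ZonationResult(
        years=years,
        merges=merges,
        dispersion_by_k=dispersion,
        boundaries_by_k=boundaries_by_k,
    )


def broken_stick(
    zonation: ZonationResult,
    n_random: int = 1000,
    seed: int | None = 0,
    max_k: int | None = None,
) -> int:
    """Number of significant zones by Monte Carlo broken-stick comparison.

    For each split count k, the observed proportional dispersion drop
    (D[k-1] - D[k]) / D[1] is compared with the mean share of the k-th
    largest of T random-length contiguous year groups.  Scanning k upward,
    the significant count is the last k whose observed drop exceeds the
    random expectation.
    """
    if n_random < 100:
        warnings.warn("n_random < 100 gives an unstable broken-stick test")
    D = zonation.dispersion_by_k
    T = len(D)
    total = D[0]
    if total == 0:
        return 1
    if max_k is None:
        max_k = T
    rng = np.random.default_rng(seed)
    # random contiguous groupings of T years into T groups of random length:
    # segment length proportions, sorted descending, estimate the expected
    # share of dispersion claimed by the k-th split under the null
    shares = np.zeros(T)
    for _ in range(n_random):
        cuts = np.sort(rng.uniform(0.0, 1.0, size=T - 1))
        lengths = np.diff(np.concatenate(([0.0], cuts, [1.0])))
        shares += np.sort(lengths)[::-1]
    shares /= n_random

    significant_k = 1
    for k in range(2, max_k + 1):
        observed = (D[k - 2] - D[k - 1]) / total
        # the first split is held to the largest expected random share, the
        # second to the second largest, and so on
        expected = shares[k - 2]
        if observed > expected:
            significant_k = k
        else:
            break
    return significant_k


class ConstrainedClustering:
    """Sklearn-style wrapper around CONISS + broken-stick zone selection.

    Attributes after ``fit``: ``zonation_``, ``significant_k_``, ``labels_``
    (cluster index per year at the significant level), ``boundaries_``.
    """

    def __init__(self, n_random: int = 1000, seed: int | None = 0, max_k: int | None = None):
        self.n_random = n_random
        self.seed = seed
        self.max_k = max_k

    def get_params(self, deep=True):
        return {"n_random": self.n_random, "seed": self.seed, "max_k": self.max_k}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        self.zonation_ = coniss(X)
        self.significant_k_ = broken_stick(
            self.zonation_, n_random=self.n_random, seed=self.seed, max_k=self.max_k
        )
        groups = self.zonation_.clusters(self.significant_k_)
        labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        self.labels_ = labels
        self.boundaries_ = self.zonation_.boundaries_by_k[self.significant_k_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
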