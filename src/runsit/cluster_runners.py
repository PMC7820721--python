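"""Clustering runners by their annual activity pattern.

Pairwise similarity between users' 52-week run-frequency sequences is measured
with classic dynamic time warping (unit steps, |a_i - b_j| local cost, no
window constraint, anchored endpoints), and the resulting distance matrix is
clustered agglomeratively with Ward's variance-minimization linkage via the
Lance-Williams recurrence:

    d(Cx, Cy)^2 = [ (n_i + n_y) d(Ci, Cy)^2 + (n_j + n_y) d(Cj, Cy)^2
                    - n_y d(Ci, Cj)^2 ] / (n_i + n_j + n_y)

where Cx = Ci u Cj is the newly merged cluster. A ``variant="printed"``
alternative replaces the minus term with a plus and uses n(Cx) + n(Cy)
denominators; it reproduces a recurrence occasionally (mis)printed in the
applied literature and exists purely for comparison. Note Ward linkage on DTW
distances is not Euclidean-valid; it is used here regardless, as is common in
activity-pattern studies, and the dendrogram should be read as a heuristic
grouping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .preprocess import WeeklyActivityMatrix


@njit(cache=True)
def _dtw_kernel(a, b):
    n, m = len(a), len(b)
    big = 1e300
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = big
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = big
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        for j in range(m + 1):
            prev[j] = cur[j]
    return prev[m]


@njit(cache=True)
def _pairwise_kernel(X):
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_kernel(X[i], X[j])
            D[i, j] = d
            D[j, i] = d
    return D


def dtw_distance(a, b) -> float:
    """DTW distance between two sequences (minimal cumulative |a_i - b_j| cost)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    return float(_dtw_kernel(a, b))


def pairwise_dtw(matrix) -> np.ndarray:
    """Symmetric DTW distance matrix over the rows of a weekly activity matrix."""
    X = matrix.counts if isinstance(matrix, WeeklyActivityMatrix) else np.asarray(matrix)
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 users")
    return _pairwise_kernel(X)


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("diagonal must be zero")
    return D


def ward_linkage(D: np.ndarray, variant: str = "standard") -> np.ndarray:
    """Agglomerative Ward linkage on a precomputed distance matrix.

    Returns an (n-1, 4) array of merges ``[a, b, height, size]`` with new
    clusters numbered n, n+1, ... (the scipy convention). At each step the
    globally closest active pair merges; ties break on the smallest (a, b)
    index pair. ``variant="standard"`` is the Lance-Williams Ward update;
    ``variant="printed"`` the plus-term alternative described in the module
    docstring.
    """
    if variant not in ("standard", "printed"):
        raise ValueError("variant must be 'standard' or 'printed'")
    D = _check_distance_matrix(D)
    n = D.shape[0]
    total = 2 * n - 1
    big = np.inf
    M = np.full((total, total), big)
    M[:n, :n] = D
    np.fill_diagonal(M, big)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True

    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        idx = np.where(active)[0]
        sub = M[np.ix_(idx, idx)]
        mval = sub.min()
        # earliest row-major hit in the upper triangle = smallest (a, b) pair
        pos = np.argwhere(np.triu(sub <= mval, k=1))[0]
        a, b = int(idx[pos[0]]), int(idx[pos[1]])
        new = n + step
        na, nb = sizes[a], sizes[b]
        Z[step] = (a, b, mval, na + nb)

        others = idx[(idx != a) & (idx != b)]
        if others.size:
            day = M[a, others]
            dby = M[b, others]
            ny = sizes[others]
            if variant == "standard":
                d2 = ((na + ny) * day**2 + (nb + ny) * dby**2 - ny * mval**2) / (na + nb + ny)
            else:
                d2 = ((na + ny) * day**2 + (nb + ny) * dby**2 + ny * mval**2) / (na + nb + ny)
            dnew = np.sqrt(np.maximum(d2, 0.0))
            M[new, others] = dnew
            M[others, new] = dnew
        active[a] = active[b] = False
        active[new] = True
        sizes[new] = na + nb
    return Z


def cut_dendrogram(linkage: np.ndarray, threshold: float) -> np.ndarray:
    """Flat cluster labels after discarding merges with height > threshold.

    Labels are 0-based and numbered by the smallest leaf index they contain.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    Z = np.asarray(linkage)
    n = Z.shape[0] + 1
    parent = np.arange(2 * n - 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, h, _) in enumerate(Z):
        if h <= threshold:
            new = n + step
            parent[find(int(a))] = new
            parent[find(int(b))] = new
    roots = [find(i) for i in range(n)]
    labels = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in labels:
            labels[r] = len(labels)
        out[i] = labels[r]
    return out


def threshold_for_k(linkage: np.ndarray, k: int) -> float:
    """A cut height yielding exactly k clusters (midpoint of the k-th merge gap)."""
    Z = np.asarray(linkage)
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError("k must be in 1..n")
    heights = np.sort(Z[:, 2])
    if k == 1:
        return float(heights[-1])
    if k == n:
        return float(heights[0]) / 2.0
    return float((heights[n - 1 - k] + heights[n - k]) / 2.0)


def cluster_profile(labels: np.ndarray, matrix: WeeklyActivityMatrix) -> pd.DataFrame:
    """Per-cluster size, mean annual run count and mean weekly sequence."""
    labels = np.asarray(labels)
    if len(labels) != matrix.n_users:
        raise ValueError("labels do not align with matrix rows")
    annual = matrix.annual_run_counts()
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        rows.append(
            {
                "cluster": int(c),
                "n_users": int(sel.sum()),
                "mean_annual_runs": float(annual[sel].mean()),
                "mean_weekly_sequence": matrix.counts[sel].mean(axis=0),
            }
        )
    return pd.DataFrame(rows)
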