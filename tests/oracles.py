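"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy.cluster / the package's own code paths: naive
O(n^3) agglomeration with explicit Lance-Williams updates, and full
enumeration of the Mann-Whitney null distribution.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def naive_ward(x: np.ndarray):
    """Naive Ward agglomeration; returns the cophenetic distance matrix and
    the sorted merge heights.

    Cluster distance: d(A,B) = sqrt(2 |A||B| / (|A|+|B|)) * ||c_A - c_B||,
    which reproduces the heights of standard Ward linkage on Euclidean
    distances.  Ties break on the lowest pair index.
    """
    n = x.shape[0]
    clusters = {i: [i] for i in range(n)}
    centroid = {i: x[i].astype(float) for i in range(n)}
    coph = np.zeros((n, n))
    heights = []

    def dist(a, b):
        na, nb = len(clusters[a]), len(clusters[b])
        return np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(centroid[a] - centroid[b])

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = dist(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        na, nb = len(clusters[a]), len(clusters[b])
        centroid[a] = (na * centroid[a] + nb * centroid[b]) / (na + nb)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b], centroid[b]
    return coph, np.sort(np.asarray(heights))


def naive_complete(d0: np.ndarray):
    """Naive complete-linkage agglomeration on a precomputed distance matrix;
    returns the cophenetic matrix and sorted merge heights."""
    n = d0.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []

    def dist(a, b):
        return max(d0[i, j] for i in clusters[a] for j in clusters[b])

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = dist(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph, np.sort(np.asarray(heights))


def mann_whitney_exact_pmf(n1: int, n2: int) -> dict[float, float]:
    """Null pmf of U1 over all tie-free rank assignments (full enumeration)."""
    total = comb(n1 + n2, n1)
    counts: dict[float, int] = {}
    for c in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(c) - n1 * (n1 + 1) / 2.0
        counts[u] = counts.get(u, 0) + 1
    return {u: k / total for u, k in counts.items()}


def mann_whitney_exact_p(pmf: dict[float, float], u: float) -> float:
    """Exact two-sided p: doubled smaller tail including the point, capped."""
    lo = sum(v for k, v in pmf.items() if k <= u)
    hi = sum(v for k, v in pmf.items() if k >= u)
    return min(1.0, 2.0 * min(lo, hi))
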