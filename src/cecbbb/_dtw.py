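"""Dynamic time warping with a Sakoe-Chiba band.

The point cost is the squared amplitude difference; the returned distance is
the square root of the minimal cumulative cost over monotone warping paths
restricted to |i - j| <= band_radius. A radius at least as large as the
sequence length reproduces unconstrained DTW.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .exceptions import InvalidInputError


@njit(cache=True)
def _dtw_band(x, y, radius):  # pragma: no cover - exercised via dtw_distance
    n = x.shape[0]
    m = y.shape[0]
    inf = np.inf
    prev = np.full(m + 1, inf)
    cur = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = inf
        lo = i - radius
        if lo < 1:
            lo = 1
        hi = i + radius
        if hi > m:
            hi = m
        for j in range(lo, hi + 1):
            d = x[i - 1] - y[j - 1]
            c = d * d
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _pairwise_dtw(X, radius):  # pragma: no cover
    n = X.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = _dtw_band(X[a], X[b], radius)
            out[a, b] = np.sqrt(d)
            out[b, a] = out[a, b]
    return out


def dtw_distance(x, y, band_radius: int | None = None) -> float:
    """Band-constrained DTW distance between two 1-D sequences.

    ``band_radius=None`` means unconstrained. For unequal lengths the band
    must be wide enough (radius >= |len(x) - len(y)|) for a monotone path to
    exist.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.size == 0 or y.size == 0:
        raise InvalidInputError("dtw_distance requires two non-empty 1-D sequences")
    if band_radius is None:
        band_radius = max(x.size, y.size)
    band_radius = int(band_radius)
    if band_radius < 0:
        raise InvalidInputError("band_radius must be non-negative")
    if band_radius < abs(x.size - y.size):
        raise InvalidInputError(
            f"band radius {band_radius} infeasible for lengths "
            f"{x.size} and {y.size}"
        )
    return float(np.sqrt(_dtw_band(x, y, band_radius)))


def pairwise_dtw(X: np.ndarray, band_radius: int) -> np.ndarray:
    """Symmetric matrix of band-constrained DTW distances between rows of X."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidInputError("X must be a 2-D array of equal-length sequences")
    return _pairwise_dtw(X, int(band_radius))


def cross_dtw(A: np.ndarray, B: np.ndarray, band_radius: int) -> np.ndarray:
    """Distance matrix between rows of A (queries) and rows of B (references)."""
    A = np.ascontiguousarray(A, dtype=np.float64)
    B = np.ascontiguousarray(B, dtype=np.float64)
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = np.sqrt(_dtw_band(A[i], B[j], int(band_radius)))
    return out
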