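"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code with the package:
exhaustive warping-path enumeration for DTW, an explicit-sum DFT sliding
window SFA, and normal-equations least squares.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def dtw_bruteforce(x, y, band_radius=None) -> float:
    """Minimal cumulative squared-difference cost over all monotone warping
    paths, by explicit path enumeration. Exponential; keep sequences short."""
    x = list(map(float, x))
    y = list(map(float, y))
    n, m = len(x), len(y)
    r = max(n, m) if band_radius is None else band_radius
    best = [math.inf]

    def walk(i, j, cost):
        if abs(i - j) > r:
            return
        cost += (x[i] - y[j]) ** 2
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])


def sfa_word_counts_naive(series, window_size, word_length, breakpoints):
    """Word -> count mapping via per-window explicit-sum DFT and quantization.

    Windows are z-normalized with the population SD; Fourier components are
    [Re c1, Im c1, Re c2, ...] of the explicit DFT sum; quantization counts
    breakpoints <= value; consecutive duplicate words are collapsed before
    counting.
    """
    s = [float(v) for v in series]
    words = []
    for start in range(len(s) - window_size + 1):
        w = s[start:start + window_size]
        mu = sum(w) / window_size
        sd = math.sqrt(sum((v - mu) ** 2 for v in w) / window_size)
        if sd == 0:
            z = [0.0] * window_size
        else:
            z = [(v - mu) / sd for v in w]
        feats = []
        k = 1
        while len(feats) < word_length:
            c = sum(z[t] * cmath.exp(-2j * math.pi * k * t / window_size)
                    for t in range(window_size))
            feats.extend([c.real, c.imag])
            k += 1
        feats = [round(v, 8) for v in feats[:word_length]]
        symbols = tuple(
            sum(1 for b in breakpoints[c] if v >= b)
            for c, v in enumerate(feats)
        )
        words.append(symbols)
    reduced = []
    for w in words:
        if not reduced or reduced[-1] != w:
            reduced.append(w)
    counts = {}
    for w in reduced:
        counts[w] = counts.get(w, 0) + 1
    return counts


def ols_normal_equations(X, y):
    """Least-squares coefficients by solving (X'X) b = X'y directly."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
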