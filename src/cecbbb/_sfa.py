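"""Symbolic Fourier Approximation of sliding windows.

Each stride-1 window is z-normalized, transformed by a real FFT, and the
first ``word_length`` real-valued components (real/imaginary parts of the
non-mean coefficients, interleaved) are quantized per component into an
alphabet via supplied breakpoints. Consecutive duplicate words are collapsed
(numerosity reduction).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigError


def max_word_length(window_size: int) -> int:
    return 2 * (window_size // 2)


def window_fourier_features(
    signal: np.ndarray, window_size: int, word_length: int
) -> np.ndarray:
    """Per-window truncated Fourier features, shape (n_windows, word_length)."""
    signal = np.asarray(signal, dtype=float)
    if window_size > signal.size:
        raise ConfigError(
            f"window_size {window_size} exceeds series length {signal.size}"
        )
    if word_length > max_word_length(window_size):
        raise ConfigError(
            f"word_length {word_length} exceeds the {max_word_length(window_size)} "
            f"available Fourier components of a {window_size}-sample window"
        )
    win = sliding_window_view(signal, window_size).astype(float)
    mu = win.mean(axis=1, keepdims=True)
    sd = win.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    win = (win - mu) / sd
    spec = np.fft.rfft(win, axis=1)[:, 1:]  # drop the (zero) mean coefficient
    feats = np.empty((win.shape[0], 2 * spec.shape[1]))
    feats[:, 0::2] = spec.real
    feats[:, 1::2] = spec.imag
    # breakpoints are quantiles of these values, so exact ties are routine;
    # fixed 1e-8 rounding keeps quantization stable under float noise
    return np.round(feats[:, :word_length], 8)


def learn_breakpoints(features: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin edges per Fourier component, shape (word_length, n_bins-1)."""
    if n_bins < 2:
        raise ConfigError("n_bins must be at least 2")
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    return np.quantile(features, qs, axis=0).T


def quantize(features: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    """Symbol matrix (n_windows, word_length) of per-component bin indices."""
    symbols = np.empty(features.shape, dtype=np.int64)
    for c in range(features.shape[1]):
        symbols[:, c] = np.searchsorted(breakpoints[c], features[:, c], side="right")
    return symbols


def numerosity_reduce(words: list[tuple]) -> list[tuple]:
    out = []
    for w in words:
        if not out or out[-1] != w:
            out.append(w)
    return out


def sfa_words(
    signal: np.ndarray,
    window_size: int,
    word_length: int,
    breakpoints: np.ndarray,
) -> list[tuple]:
    """SFA word sequence of one series, numerosity-reduced."""
    feats = window_fourier_features(signal, window_size, word_length)
    symbols = quantize(feats, breakpoints)
    return numerosity_reduce([tuple(row) for row in symbols])
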