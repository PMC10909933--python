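"""Lempel-Ziv (LZ76) complexity of symbolic sequences.

The complexity of a sequence is the number of phrases in its exhaustive
history: the parsing in which each new phrase is the shortest substring
not reproducible (with copy-extension) from the already-parsed prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the inner scan; pure-python fallback is identical
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["lempel_ziv_complexity", "sliding_lzc", "ComplexityTrace"]


@njit(cache=True)
def _lz76_count(s: np.ndarray) -> int:
    # Kaspar-Schuster scan; s is a 1-D integer array
    n = s.shape[0]
    c = 1
    l = 1
    i = 0
    k = 1
    kmax = 1
    while l + k <= n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    if k != 1:
        c += 1
    return c


def _as_int_array(symbols) -> np.ndarray:
    if isinstance(symbols, str):
        arr = np.array([ord(ch) for ch in symbols], dtype=np.int64)
        return arr
    arr = np.asarray(symbols)
    if arr.ndim != 1:
        raise ValueError("symbol sequence must be 1-D")
    if not np.issubdtype(arr.dtype, np.integer):
        _, arr = np.unique(arr, return_inverse=True)
    return arr.astype(np.int64)


def lempel_ziv_complexity(symbols) -> int:
    """LZ76 phrase count of a sequence (string or 1-D array of symbols)."""
    arr = _as_int_array(symbols)
    if arr.size == 0:
        raise ValueError("empty sequence")
    return int(_lz76_count(arr))


@dataclass
class ComplexityTrace:
    """Windowed LZ76 complexity with an explicit time axis."""

    times_ms: np.ndarray
    value: np.ndarray
    window_ms: float
    mode: str  #: "sliding" or "tiled"


def sliding_lzc(labels, window_ms: float = 100.0, fs: float = 1000.0,
                mode: str = "sliding", normalize: bool = False) -> ComplexityTrace:
    """Windowed LZ76 complexity of a label sequence.

    mode="sliding": centered window at every sample, NaN where the full
    window does not fit.  mode="tiled": non-overlapping bins; one value
    per bin, timestamped at the bin center.  ``normalize`` divides each
    count by ``w / log2(w)`` (the random-sequence asymptotic scale).
    """
    arr = _as_int_array(labels)
    n = arr.size
    w = int(round(window_ms * fs / 1000.0))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > n:
        raise ValueError(f"window ({w} samples) longer than sequence ({n})")
    scale = (w / np.log2(w)) if normalize else 1.0

    if mode == "sliding":
        values = np.full(n, np.nan)
        left = (w - 1) // 2
        for i in range(n - w + 1):
            values[i + left] = _lz76_count(arr[i : i + w])
        times = np.arange(n) * 1000.0 / fs
    elif mode == "tiled":
        n_bins = n // w
        values = np.empty(n_bins)
        times = np.empty(n_bins)
        for b in range(n_bins):
            values[b] = _lz76_count(arr[b * w : (b + 1) * w])
            times[b] = (b + 0.5) * w * 1000.0 / fs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ComplexityTrace(times_ms=times, value=values / scale,
                           window_ms=window_ms, mode=mode)
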