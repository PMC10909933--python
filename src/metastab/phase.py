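"""Band-limited phase extraction, Kuramoto order parameter, metastability.

The order parameter of N phases is the modulus r (and mean angle psi) of
``(1/N) sum_j exp(i theta_j)``; its standard deviation over a sliding
window operationalizes metastability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve, firwin, hilbert

from .containers import EpochedEEG

__all__ = [
    "PhaseTensor",
    "KOPTrace",
    "MetastabilityTrace",
    "extract_phase",
    "kop",
    "kop_trace",
    "sliding_metastability",
    "baseline_normalize",
    "average_over",
    "bandpass",
]


@dataclass
class PhaseTensor:
    """Instantaneous phase per (epoch, channel, sample), wrapped to (-pi, pi]."""

    phase: np.ndarray
    band: tuple[float, float]
    fs: float
    channel_names: list[str]
    margin: int = 0  #: samples at each edge inside the filter transient

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]


@dataclass
class KOPTrace:
    """Order-parameter time series r(t), psi(t) per epoch."""

    r: np.ndarray  #: (n_epochs, n_samples), in [0, 1]
    psi: np.ndarray
    channel_set: list[str]
    fs: float
    band: tuple[float, float] | None = None
    margin: int = 0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.r.shape[-1]) * 1000.0 / self.fs


@dataclass
class MetastabilityTrace:
    """Windowed standard deviation of a KOP trace.

    ``value`` keeps the leading (epoch) axes of its source; positions
    where the window lacks full support are NaN.
    """

    value: np.ndarray
    window_ms: float
    fs: float
    stride: int = 1
    band: tuple[float, float] | None = None
    baseline_pct: np.ndarray | None = None
    n: np.ndarray | None = None  #: contributing count per point after averaging

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.value.shape[-1]) * self.stride * 1000.0 / self.fs


def _fir_bandpass_taps(band: tuple[float, float], fs: float,
                       n_samples: int | None = None) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got {band}")
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz >= Nyquist ({fs / 2} Hz)")
    trans = max(0.25 * lo, 1.0)  # transition width: 25% of the lower edge
    numtaps = int(np.ceil(3.3 * fs / trans))
    if n_samples is not None:
        # short records cannot support very sharp filters, and a long kernel
        # smears pulse-locked structure across analysis windows; cap the
        # length at an eighth of the record
        numtaps = min(numtaps, max(3, (n_samples - 1) // 8))
    numtaps |= 1  # odd length, linear phase type I
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def bandpass(data: np.ndarray, band: tuple[float, float], fs: float) -> tuple[np.ndarray, int]:
    """Zero-phase FIR band-pass along the last axis.

    The window-design taps are symmetric (linear phase), so a single
    centered convolution is already zero-phase.  Edges are reflect-padded;
    the returned margin (half the filter length) marks samples still
    inside the edge transient.
    """
    data = np.asarray(data, dtype=float)
    taps = _fir_bandpass_taps(band, fs, n_samples=data.shape[-1])
    half = len(taps) // 2
    pad = [(0, 0)] * (data.ndim - 1) + [(half, half)]
    padded = np.pad(data, pad, mode="reflect")
    shape = [1] * (data.ndim - 1) + [len(taps)]
    filtered = fftconvolve(padded, taps.reshape(shape), mode="same", axes=-1)
    filtered = filtered[..., half : half + data.shape[-1]]
    return filtered, half


def extract_phase(eeg: EpochedEEG, band: tuple[float, float]) -> PhaseTensor:
    """Band-pass filter and extract instantaneous phase per channel.

    Zero-phase FIR filtering followed by the analytic-signal angle.
    Samples within ``margin`` of either epoch edge sit inside the filter
    transient and should be excluded from inference.
    """
    filtered, margin = bandpass(eeg.data, band, eeg.fs)
    analytic = hilbert(filtered, axis=-1)
    phase = np.angle(analytic)
    phase[phase == -np.pi] = np.pi  # wrap convention (-pi, pi]
    return PhaseTensor(
        phase=phase,
        band=tuple(band),
        fs=eeg.fs,
        channel_names=list(eeg.channel_names),
        margin=margin,
    )


def kop(phases: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Order parameter of a set of phases.

    Parameters
    ----------
    phases : ndarray
        Phases in radians; reduced along ``axis`` (the channel axis).

    Returns
    -------
    r : modulus of the mean unit phasor, in [0, 1]
    psi : argument of the mean phasor
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape[axis] < 1:
        raise ValueError("empty channel set")
    z = np.exp(1j * phases).mean(axis=axis)
    return np.abs(z), np.angle(z)


def kop_trace(phase: PhaseTensor, channels=None) -> KOPTrace:
    """Compute r(t), psi(t) per epoch over a channel subset.

    ``channels`` may be labels or indices; default all channels.
    """
    if channels is None:
        idx = np.arange(len(phase.channel_names))
        labels = list(phase.channel_names)
    elif all(isinstance(c, str) for c in channels):
        lookup = {n: i for i, n in enumerate(phase.channel_names)}
        idx = np.array([lookup[c] for c in channels], dtype=np.intp)
        labels = list(channels)
    else:
        idx = np.asarray(channels, dtype=np.intp)
        labels = [phase.channel_names[i] for i in idx]
    if idx.size < 2:
        raise ValueError("KOP requires at least 2 channels")
    r, psi = kop(phase.phase[:, idx, :], axis=1)
    return KOPTrace(
        r=r, psi=psi, channel_set=labels, fs=phase.fs,
        band=phase.band, margin=phase.margin,
    )


def window_samples(window_ms: float, fs: float) -> int:
    w = int(round(window_ms * fs / 1000.0))
    if w < 2:
        raise ValueError(f"window of {window_ms} ms spans {w} sample(s); need >= 2")
    return w


def sliding_metastability(trace: KOPTrace, window_ms: float = 50.0,
                          stride: int = 1) -> MetastabilityTrace:
    """Population std of r in a centered sliding window.

    A window of w samples centered at sample i covers
    ``[i - (w-1)//2, i + w//2]``; positions without full support are NaN.
    """
    w = window_samples(window_ms, trace.fs)
    r = np.asarray(trace.r, dtype=float)
    n = r.shape[-1]
    if w > n:
        raise ValueError(f"window ({w} samples) longer than trace ({n})")
    windows = sliding_window_view(r, w, axis=-1)
    std = windows.std(axis=-1)  # population std (ddof=0)
    out = np.full(r.shape, np.nan)
    left = (w - 1) // 2
    out[..., left : left + std.shape[-1]] = std
    if stride > 1:
        out = out[..., ::stride]
    return MetastabilityTrace(
        value=out, window_ms=window_ms, fs=trace.fs / stride if stride > 1 else trace.fs,
        stride=1, band=trace.band,
    )


def baseline_normalize(trace: MetastabilityTrace,
                       baseline_interval_ms: tuple[float, float]) -> MetastabilityTrace:
    """Express a trace as percent of its mean over a baseline interval."""
    lo, hi = baseline_interval_ms
    times = trace.times_ms
    mask = (times >= lo) & (times <= hi)
    if not mask.any() or lo < times[0] or hi > times[-1]:
        raise ValueError(
            f"baseline interval [{lo}, {hi}] ms outside trace support "
            f"[{times[0]:.6g}, {times[-1]:.6g}] ms"
        )
    sub = trace.value[..., mask]
    if np.isnan(sub).all():
        raise ValueError("baseline interval contains only NaN")
    base = np.nanmean(sub)
    if not np.isfinite(base) or base == 0:
        raise ValueError(f"degenerate baseline mean {base}")
    pct = 100.0 * trace.value / base
    return MetastabilityTrace(
        value=trace.value, window_ms=trace.window_ms, fs=trace.fs,
        stride=trace.stride, band=trace.band, baseline_pct=pct, n=trace.n,
    )


def average_over(values, return_n: bool = False):
    """Pointwise NaN-ignoring mean over the leading axis/axes of stacked traces.

    ``values`` is a sequence of equally shaped arrays (epochs or
    subjects).  Returns the mean trace, plus per-point contribution
    counts when ``return_n``.
    """
    arr = np.asarray([np.asarray(v, dtype=float) for v in values])
    if arr.ndim < 2:
        raise ValueError("need a stack of traces")
    flat = arr.reshape(-1, arr.shape[-1])
    n = np.sum(~np.isnan(flat), axis=0)
    mean = np.full(flat.shape[-1], np.nan)
    has = n > 0
    with np.errstate(invalid="ignore"):
        mean[has] = np.nanmean(flat[:, has], axis=0)
    if return_n:
        return mean, n
    return mean
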