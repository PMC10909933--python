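"""Microstate derivation and backfitting.

Template topographies are clustered from GFP-peak maps by atomise-and-
agglomerate hierarchical clustering (TAAHC); the number of states is
chosen with the Krzanowski-Lai elbow index on the correlation-sum curve;
data are then backfitted to a polarity-invariant label sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .grouping import global_field_power

logger = logging.getLogger(__name__)

__all__ = [
    "MicrostateModel",
    "LabelSequence",
    "gfp_peaks",
    "taahc",
    "select_k_krzanowski_lai",
    "backfit",
    "transition_probabilities",
    "fit_microstates",
]


@dataclass
class MicrostateModel:
    """k unit-norm template topographies plus the TAAHC fit curve."""

    templates: np.ndarray  #: (k, n_channels), mean-free, unit-norm
    k: int
    correlation_sum_by_k: dict[int, float]
    chosen_k_criterion: dict[int, float] = field(default_factory=dict)
    templates_by_k: dict[int, np.ndarray] = field(default_factory=dict)
    n_maps: int = 0


@dataclass
class LabelSequence:
    labels: np.ndarray  #: per-sample microstate index in [0, k)
    fs: float
    gev: float  #: global explained variance of the fit, in [0, 1]


def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def _spatial_corr(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels, (n_maps, k)."""
    m = _center(np.atleast_2d(maps))
    t = _center(np.atleast_2d(templates))
    m_norm = np.linalg.norm(m, axis=1, keepdims=True)
    t_norm = np.linalg.norm(t, axis=1, keepdims=True)
    m_norm[m_norm == 0] = 1.0
    t_norm[t_norm == 0] = 1.0
    return (m / m_norm) @ (t / t_norm).T


def gfp_peaks(data: np.ndarray, min_peaks: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Channel maps at local maxima of the GFP trace.

    ``data`` is (n_channels, n_samples).  A flat maximum contributes its
    first sample.  Returns ``(peak_indices, maps)`` with maps shaped
    (n_peaks, n_channels).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need (n_channels, n_samples) with >= 3 samples")
    gfp = global_field_power(data)
    peaks, props = find_peaks(gfp, plateau_size=1)
    idx = props["left_edges"] if "left_edges" in props else peaks
    if idx.size < min_peaks:
        raise ValueError(f"found {idx.size} GFP peaks, need >= {min_peaks}")
    return idx, data[:, idx].T


def _principal_template(members: np.ndarray) -> np.ndarray:
    """First principal axis of member maps, sign-aligned to the majority."""
    m = _center(members)
    if m.shape[0] == 1:
        v = m[0]
        n = np.linalg.norm(v)
        return v / n if n > 0 else v
    # right singular vector of the member matrix
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    v = vt[0]
    if np.sum(m @ v) < 0:
        v = -v
    return v


def taahc(maps: np.ndarray, k_min: int = 2, k_max: int = 10) -> MicrostateModel:
    """Atomise-and-agglomerate hierarchical clustering of topographies.

    Starting from singleton clusters, the cluster with the lowest
    correlation sum (sum over members of \\|spatial correlation\\| with its
    template) is dissolved and its members reassigned to the remaining
    cluster of highest \\|correlation\\|.  The total correlation sum is
    recorded at every k from ``k_max`` down to ``k_min``.
    """
    maps = np.asarray(maps, dtype=float)
    n_maps = maps.shape[0]
    if k_max > n_maps:
        raise ValueError(f"k_max={k_max} exceeds number of maps ({n_maps})")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")

    clusters: list[list[int]] = [[i] for i in range(n_maps)]
    templates = [_principal_template(maps[c]) for c in clusters]
    cs_by_k: dict[int, float] = {}
    templates_by_k: dict[int, np.ndarray] = {}

    while len(clusters) >= k_min:
        k = len(clusters)
        tmpl = np.asarray(templates)
        corr = np.abs(_spatial_corr(maps, tmpl))
        cluster_cs = np.array(
            [np.sum(corr[c, ci]) for ci, c in enumerate(clusters)]
        )
        if k <= k_max:
            cs_by_k[k] = float(cluster_cs.sum())
            templates_by_k[k] = tmpl.copy()
        if k == k_min:
            break
        worst = int(np.argmin(cluster_cs))
        orphans = clusters.pop(worst)
        templates.pop(worst)
        rest = np.abs(_spatial_corr(maps[orphans], np.asarray(templates)))
        touched = set()
        for member, row in zip(orphans, rest):
            target = int(np.argmax(row))
            clusters[target].append(member)
            touched.add(target)
        for ci in touched:
            templates[ci] = _principal_template(maps[clusters[ci]])

    return MicrostateModel(
        templates=templates_by_k[min(templates_by_k)],
        k=min(templates_by_k),
        correlation_sum_by_k=cs_by_k,
        templates_by_k=templates_by_k,
        n_maps=n_maps,
    )


def select_k_krzanowski_lai(correlation_sum_by_k: dict[int, float],
                            n_channels: int, n_maps: int) -> int:
    """Krzanowski-Lai elbow index over the correlation-sum curve.

    Dispersion is ``D_k = n_maps - CS_k``; ``DIFF(k) = (k-1)^{2/p} D_{k-1}
    - k^{2/p} D_k`` with p = n_channels; the chosen k maximizes
    ``|DIFF(k) / DIFF(k+1)|`` over interior k (earliest max on ties).
    """
    ks = sorted(correlation_sum_by_k)
    if len(ks) < 4 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 4 consecutive k values")
    p = float(n_channels)
    D = {k: n_maps - correlation_sum_by_k[k] for k in ks}
    diff = {
        k: (k - 1) ** (2.0 / p) * D[k - 1] - k ** (2.0 / p) * D[k]
        for k in ks[1:]
    }
    interior = ks[1:-1]
    eps = 1e-12
    kl = {}
    for k in interior:
        denom = abs(diff[k + 1])
        kl[k] = abs(diff[k]) / max(denom, eps)
    values = np.array([kl[k] for k in interior])
    if np.ptp(values) < 1e-3 * max(1.0, values.max()):
        warnings.warn("KL index nearly constant (no elbow); returning earliest k")
        return interior[0]
    return interior[int(np.argmax(values))]


def backfit(data: np.ndarray, templates: np.ndarray, fs: float = 1000.0) -> LabelSequence:
    """Label each sample with its best-matching template (polarity-invariant).

    ``data`` is (n_channels, n_samples).  GEV is the GFP-weighted squared
    correlation between each map and its winning template; zero-variance
    samples get label 0 and are excluded from GEV.
    """
    data = np.asarray(data, dtype=float)
    maps = data.T  # (n_samples, n_channels)
    corr = np.abs(_spatial_corr(maps, templates))
    labels = np.argmax(corr, axis=1)
    gfp = global_field_power(data)
    valid = gfp > 0
    labels = np.where(valid, labels, 0)
    best = corr[np.arange(corr.shape[0]), labels]
    denom = np.sum(gfp[valid] ** 2)
    gev = float(np.sum((gfp[valid] * best[valid]) ** 2) / denom) if denom > 0 else 0.0
    return LabelSequence(labels=labels.astype(np.int64), fs=fs, gev=gev)


def transition_probabilities(labels: np.ndarray, k: int | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic matrix of transitions between distinct successive labels.

    Self-transitions (label persistence) are excluded.  Returns the
    matrix and a boolean vector flagging rows with no observed exits
    (left all-zero).
    """
    labels = np.asarray(labels).ravel()
    if labels.size < 2:
        raise ValueError("need at least 2 samples")
    if k is None:
        k = int(labels.max()) + 1
    counts = np.zeros((k, k))
    src, dst = labels[:-1], labels[1:]
    change = src != dst
    np.add.at(counts, (src[change], dst[change]), 1)
    totals = counts.sum(axis=1)
    flagged = totals == 0
    probs = np.zeros_like(counts)
    nz = ~flagged
    probs[nz] = counts[nz] / totals[nz, None]
    if flagged.all():
        logger.warning("degenerate label sequence: no transitions at all")
    return probs, flagged


def fit_microstates(rest_data: np.ndarray, fs: float, band=(8.0, 12.0),
                    k_min: int = 2, k_max: int = 10) -> MicrostateModel:
    """Full per-subject fitting path: alpha band-pass, GFP peaks, TAAHC, KL.

    ``rest_data`` is a continuous (n_channels, n_samples) resting record.
    """
    from .phase import bandpass

    filtered, _ = bandpass(rest_data, band, fs)
    _, maps = gfp_peaks(filtered)
    k_max_eff = min(k_max, maps.shape[0] - 1)
    model = taahc(maps, k_min=k_min, k_max=k_max_eff)
    k_star = select_k_krzanowski_lai(
        model.correlation_sum_by_k, rest_data.shape[0], model.n_maps
    )
    model.k = k_star
    model.templates = model.templates_by_k[k_star]
    return model
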