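"""Synthetic EEG cohorts and connectomes with planted, recoverable structure.

The generative model plants exactly the features the analysis pipeline
measures: metastable alpha-band synchrony among a handful of phase-
oscillator sources, a small set of quasi-stable sensor topographies that
dominate alternately (microstate-like structure), and - in the stimulated
condition - a pulse that phase-resets a local source cluster, pins the
active topography, and adds a biphasic evoked deflection.

Source phases are integrated with the same delayed-Kuramoto kernel as the
connectome model (zero delays, all-to-all coupling).  All randomness
derives from ``numpy.random.default_rng`` seeded with
``[cohort_seed, subject, stream, ...]`` tuples, so output is reproducible
bit-for-bit across platforms (NumPy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import delayed_kuramoto
from .containers import Connectome, ContinuousEEG, EpochedEEG

__all__ = [
    "SyntheticConnectomeSpec",
    "SyntheticCohortSpec",
    "generate_connectome",
    "generate_resting_eeg",
    "generate_resting_record",
    "generate_tms_epochs",
]


@dataclass
class SyntheticConnectomeSpec:
    n_nodes: int = 90
    sphere_radius_mm: float = 70.0
    decay_length_mm: float = 35.0
    conduction_velocity_m_s: float = 7.0
    min_distance_mm: float = 12.0  #: parcel centroids never coincide
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.conduction_velocity_m_s <= 0:
            raise ValueError("conduction velocity must be positive")


def generate_connectome(spec: SyntheticConnectomeSpec) -> Connectome:
    """Distance-decaying weighted network on seeded points in a ball.

    ``w_ij = exp(-d_ij / decay_length)`` with zero diagonal; delays are
    ``d_ij / velocity`` (mm over mm/ms, i.e. ms, since 1 m/s = 1 mm/ms).
    """
    rng = np.random.default_rng(spec.seed)

    def _draw(n):
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = spec.sphere_radius_mm * rng.uniform(0, 1, n) ** (1 / 3)
        return direction * radius[:, None]

    # Poisson-disk style rejection: keep resampling points that crowd others
    coords = _draw(spec.n_nodes)
    for _ in range(200):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        crowded = np.flatnonzero(dist.min(axis=1) < spec.min_distance_mm)
        if crowded.size == 0:
            break
        coords[crowded] = _draw(crowded.size)
    else:
        raise RuntimeError("could not satisfy min_distance_mm; lower it or n_nodes")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    weights = np.exp(-dist / spec.decay_length_mm)
    np.fill_diagonal(weights, 0.0)
    delays = dist / spec.conduction_velocity_m_s
    return Connectome(weights=weights, distances=dist, delays=delays,
                      coordinates=coords)


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort (all subjects share the spec)."""

    n_subjects: int = 20
    n_epochs: int = 60
    n_channels: int = 32
    fs: float = 1000.0
    epoch_ms: float = 2000.0
    pulse_ms: float = 500.0
    n_sources: int = 8
    source_bands: tuple = ((8.0, 12.0),)
    reset_strength: float = 1.0
    recovery_tau_ms: float = 350.0
    evoked_amplitude: float = 5.0  # uV at the deflection peak
    ringing_amp_uv: float = 10.0  #: phase-locked evoked alpha ringing
    ringing_freq_hz: float = 9.0
    ringing_tau_ms: float = 250.0
    anticipation_effect: bool = False
    seed: int = 0
    # generative knobs (defaults give a clearly metastable working point)
    n_templates: int = 4
    source_coupling: float = 0.012
    source_noise: float = 1.8  #: rad/sqrt(s), like TwinParams.noise_scale
    sim_dt_ms: float = 0.5
    mixing: str = "smooth"  #: "smooth" or "identity"
    mixing_amp_uv: float = 5.0
    mixing_sigma_mm: float = 22.0
    template_amp_uv: float = 6.0
    sensor_noise_uv: float = 1.0
    dwell_mean_ms: float = 100.0
    cluster_fraction: float = 0.5  #: share of sources the pulse resets
    background_mix_factor: float = 1.0  #: non-cluster source gain
    background_suppression: float = 0.15  #: residual background gain at the pulse

    def __post_init__(self) -> None:
        if not 0 <= self.pulse_ms < self.epoch_ms:
            raise ValueError("pulse must lie within the epoch")
        if self.n_sources < 2:
            raise ValueError("need at least 2 sources")
        if not 0.0 <= self.reset_strength <= 1.0:
            raise ValueError("reset_strength must be in [0, 1]")
        if self.mixing == "identity" and self.n_channels != self.n_sources:
            raise ValueError("identity mixing requires n_channels == n_sources")

    @property
    def n_cluster(self) -> int:
        return max(2, int(round(self.cluster_fraction * self.n_sources)))


def _fibonacci_hemisphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n  # upper half only
    phi = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _smooth_random_fields(positions: np.ndarray, n_fields: int, rng,
                          length_mm: float = 45.0) -> np.ndarray:
    """Spatially smooth random channel patterns, centered and orthonormal."""
    diff = positions[:, None, :] - positions[None, :, :]
    kern = np.exp(-((diff**2).sum(-1)) / (2 * length_mm**2))
    raw = kern @ rng.standard_normal((positions.shape[0], n_fields))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    return q.T  # (n_fields, n_channels), unit-norm rows


@dataclass
class _Geometry:
    channel_positions: np.ndarray
    source_positions: np.ndarray
    mixing: np.ndarray  # (n_channels, n_sources), scaled to uV
    templates: np.ndarray  # (n_templates, n_channels)
    evoked_profile: np.ndarray  # (n_channels,), dipolar, max |.| = 1
    ring_profile: np.ndarray  # (n_channels,), cluster blob, max = 1
    cluster_sources: np.ndarray
    cluster_channels: np.ndarray
    omega: np.ndarray  # source intrinsic frequencies, rad/ms
    site_direction: np.ndarray = field(default=None)


def _subject_geometry(spec: SyntheticCohortSpec, subject: int) -> _Geometry:
    rng = np.random.default_rng([spec.seed, subject, 0])
    ch_pos = _fibonacci_hemisphere(spec.n_channels, 95.0)
    site_dir = np.array([np.cos(np.pi / 4), -0.3, np.sin(np.pi / 4)])
    site_dir /= np.linalg.norm(site_dir)

    n_cl = spec.n_cluster
    cluster_sources = np.arange(n_cl)
    src_pos = np.empty((spec.n_sources, 3))
    # cluster sources: tight cap around the site direction
    for s in range(n_cl):
        jitter = rng.standard_normal(3) * 0.25
        v = site_dir + jitter
        v[2] = abs(v[2])
        src_pos[s] = 70.0 * v / np.linalg.norm(v)
    # remaining sources: spread over the hemisphere, away from the cap
    rest = _fibonacci_hemisphere(spec.n_sources - n_cl + 4, 70.0)
    rest = rest[np.argsort(rest @ site_dir)][: spec.n_sources - n_cl]
    src_pos[n_cl:] = rest

    if spec.mixing == "identity":
        mixing = np.eye(spec.n_channels)
    else:
        # sharp spatial falloff: each channel is dominated by its nearest
        # source, so channel phases inherit the source phase diversity
        d = np.linalg.norm(ch_pos[:, None, :] - src_pos[None, :, :], axis=-1)
        mixing = np.exp(-(d**2) / (2 * spec.mixing_sigma_mm**2))
        row = np.linalg.norm(mixing, axis=1, keepdims=True)
        mixing = mixing / (row * np.sqrt(0.5)) * spec.mixing_amp_uv
        # the stimulated cluster projects strongly; background sources are
        # weaker, so away from the cluster the planted topographies dominate
        mixing[:, n_cl:] *= spec.background_mix_factor

    templates = _smooth_random_fields(ch_pos, spec.n_templates, rng)

    # dipolar evoked profile: sign flips across the site along a tangent
    tangent = np.cross(site_dir, [0.0, 0.0, 1.0])
    tangent /= np.linalg.norm(tangent)
    rel = ch_pos - 95.0 * site_dir
    gauss = np.exp(-np.linalg.norm(rel, axis=1) ** 2 / (2 * 55.0**2))
    profile = (rel @ tangent) * gauss
    profile /= np.max(np.abs(profile))

    ring_profile = mixing[:, cluster_sources].sum(axis=1)
    ring_profile = ring_profile / np.max(np.abs(ring_profile))

    load = (mixing[:, cluster_sources] ** 2).sum(axis=1)
    n_top = max(3, spec.n_channels // 3)
    cluster_channels = np.sort(np.argsort(load)[-n_top:])

    lo, hi = spec.source_bands[0]
    # cluster sources occupy the slow edge of the band; the pulse-locked
    # post-stimulus rhythm is then slower than the ongoing background
    freqs = np.linspace(lo, hi, spec.n_sources)
    omega = 2 * np.pi * freqs / 1000.0
    return _Geometry(ch_pos, src_pos, mixing, templates, profile, ring_profile,
                     cluster_sources, cluster_channels, omega, site_dir)


def _run_sources(spec: SyntheticCohortSpec, omega: np.ndarray, rng,
                 n_samples: int, anticipation_ramp: np.ndarray | None = None
                 ) -> np.ndarray:
    """Integrate the all-to-all source network; returns (n_src, n_samples)."""
    n = omega.size
    dt = spec.sim_dt_ms
    sub = max(int(round(1000.0 / spec.fs / dt)), 1)
    n_steps = n_samples * sub
    weights = np.ones((n, n)) - np.eye(n)
    lags = np.zeros((n, n), dtype=np.int64)
    noise = rng.standard_normal((n_steps, n))
    if anticipation_ramp is not None:
        noise *= np.repeat(anticipation_ramp, sub)[:n_steps, None]
    theta = np.empty((1 + n_steps, n))
    theta[0] = rng.uniform(-np.pi, np.pi, n)
    delayed_kuramoto(theta, omega, weights, lags, spec.source_coupling, dt,
                     np.sqrt(dt / 1000.0) * spec.source_noise, noise, 1,
                     np.full(n, -1, dtype=np.int64), 0.0)
    return theta[1::sub][:n_samples].T


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2 * np.pi) - np.pi


def _apply_phase_reset(theta: np.ndarray, spec: SyntheticCohortSpec,
                       omega: np.ndarray, reset_sources: np.ndarray,
                       pulse_idx: int, reset_value: float = np.pi / 2
                       ) -> np.ndarray:
    """Force reset sources to a common phase at the pulse; coherence decays
    back with time constant ``recovery_tau_ms``."""
    if reset_sources.size == 0:
        return theta
    theta = theta.copy()
    n_samp = theta.shape[1]
    t_rel = (np.arange(pulse_idx, n_samp) - pulse_idx) * 1000.0 / spec.fs
    w = np.exp(-t_rel / spec.recovery_tau_ms)
    omega_bar = omega[reset_sources].mean()
    common = reset_value + omega_bar * t_rel  # advances at the mean rate
    for s in reset_sources:
        delta = _wrap(common - theta[s, pulse_idx:])
        theta[s, pulse_idx:] = _wrap(theta[s, pulse_idx:] + w * delta)
    return theta


def _dwell_labels(spec: SyntheticCohortSpec, rng, n_samples: int) -> np.ndarray:
    """Markov-style template dwell sequence with exponential dwell times."""
    labels = np.empty(n_samples, dtype=np.int64)
    pos = 0
    current = int(rng.integers(spec.n_templates))
    min_dwell = max(int(round(0.03 * spec.fs)), 1)
    mean_dwell = spec.dwell_mean_ms * spec.fs / 1000.0
    while pos < n_samples:
        dwell = max(int(rng.exponential(mean_dwell)), min_dwell)
        labels[pos : pos + dwell] = current
        pos += dwell
        if spec.n_templates > 1:
            step = int(rng.integers(1, spec.n_templates))
            current = (current + step) % spec.n_templates
    return labels


def _evoked_wave(times_ms: np.ndarray, pulse_ms: float, amp: float) -> np.ndarray:
    """Biphasic deflection: difference of two Gaussians, peak ~30 ms post-pulse."""
    t = times_ms - pulse_ms
    wave = np.exp(-((t - 30.0) ** 2) / (2 * 10.0**2)) \
        - 0.8 * np.exp(-((t - 60.0) ** 2) / (2 * 15.0**2))
    wave[t < 0] = 0.0
    return amp * wave


def _ringing_wave(spec: SyntheticCohortSpec, times_ms: np.ndarray,
                  pulse_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-locked evoked alpha ringing, in quadrature (cos/sin) parts."""
    t = times_ms - pulse_ms
    envelope = np.where(t >= 0, np.exp(-t / spec.ringing_tau_ms), 0.0)
    phase = 2 * np.pi * spec.ringing_freq_hz * t / 1000.0
    amp = spec.ringing_amp_uv * spec.reset_strength * envelope
    return amp * np.cos(phase), amp * np.sin(phase)


def _render_epoch(spec: SyntheticCohortSpec, geo: _Geometry, theta: np.ndarray,
                  labels: np.ndarray, rng, evoked: np.ndarray | None,
                  suppression: np.ndarray | None = None) -> np.ndarray:
    """Sensor data for one epoch: mixing + active template + noise (+ ERP).

    ``suppression`` (n_samples in [0, 1]) transiently attenuates the
    non-cluster source contributions after the pulse, emulating the
    widespread inhibition that lets the stimulated topography dominate.
    """
    gains = np.ones_like(theta)
    if suppression is not None:
        gains[spec.n_cluster:, :] = 1.0 - suppression[None, :]
    data = geo.mixing @ (gains * np.cos(theta))
    if spec.template_amp_uv > 0 and spec.n_templates > 0:
        # templates ride the faster non-cluster carriers, so the ongoing
        # topography alternation is quicker than the pulse-locked ringing
        n_src = theta.shape[0]
        n_bg = max(n_src - spec.n_cluster, 1)
        carrier_src = spec.n_cluster % n_src + np.arange(spec.n_templates) % n_bg
        carriers = np.cos(theta[carrier_src])  # (n_templates, n_samples)
        t_idx = np.arange(theta.shape[1])
        template_gain = spec.template_amp_uv
        if suppression is not None:
            # the ongoing topography rotation is quieted alongside the
            # background: the reset cluster's own pattern takes over
            template_gain = spec.template_amp_uv * (1.0 - suppression)
        data = data + template_gain * geo.templates[labels].T \
            * carriers[labels, t_idx]
    if evoked is not None:
        deflection, ring_cos, ring_sin = evoked
        # quadrature pair of fixed topographies: the evoked oscillation is a
        # wave travelling from the cluster blob into the dipolar far field,
        # so a large stable pattern exists at every phase of the cycle
        data = data + geo.evoked_profile[:, None] * deflection[None, :] \
            + geo.ring_profile[:, None] * ring_cos[None, :] \
            + geo.evoked_profile[:, None] * ring_sin[None, :]
    if spec.sensor_noise_uv > 0:
        data = data + spec.sensor_noise_uv * rng.standard_normal(data.shape)
    return data


def _channel_names(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(n)]


def _generate_epochs(spec: SyntheticCohortSpec, subject: int, stimulated: bool
                     ) -> EpochedEEG:
    geo = _subject_geometry(spec, subject)
    n_samp = int(round(spec.epoch_ms * spec.fs / 1000.0))
    pulse_idx = int(round(spec.pulse_ms * spec.fs / 1000.0))
    times_ms = np.arange(n_samp) * 1000.0 / spec.fs

    n_reset = int(round(spec.reset_strength * spec.n_cluster))
    evoked = None
    if stimulated:
        ring_cos, ring_sin = _ringing_wave(spec, times_ms, spec.pulse_ms)
        evoked = (_evoked_wave(times_ms, spec.pulse_ms, spec.evoked_amplitude),
                  ring_cos, ring_sin)
    pin_ms = spec.recovery_tau_ms * spec.reset_strength if stimulated else 0.0

    data = np.empty((spec.n_epochs, spec.n_channels, n_samp))
    source_phase = np.empty((spec.n_epochs, spec.n_sources, n_samp))
    reset_subsets = []
    for e in range(spec.n_epochs):
        rng = np.random.default_rng([spec.seed, subject, 2 + int(stimulated), e])
        ramp = None
        if stimulated and spec.anticipation_effect:
            ramp = np.ones(n_samp)
            pre = (times_ms >= spec.pulse_ms - 250.0) & (times_ms < spec.pulse_ms)
            ramp[pre] = 1.0 + 2.0 * (
                times_ms[pre] - (spec.pulse_ms - 250.0)
            ) / 250.0
        theta = _run_sources(spec, geo.omega, rng, n_samp, anticipation_ramp=ramp)
        if stimulated and n_reset > 0:
            chosen = rng.choice(geo.cluster_sources, size=n_reset, replace=False)
            chosen = np.sort(chosen)
            theta = _apply_phase_reset(theta, spec, geo.omega, chosen, pulse_idx)
            reset_subsets.append(chosen)
        else:
            reset_subsets.append(np.empty(0, dtype=np.int64))
        labels = _dwell_labels(spec, rng, n_samp)
        suppression = None
        if stimulated and pin_ms > 0:
            pin = (times_ms >= spec.pulse_ms) & (times_ms < spec.pulse_ms + pin_ms)
            labels = labels.copy()
            labels[pin] = 0
            # the pulse transiently quiets the competing background so the
            # stimulated topography dominates, decaying with the same tau
            t_rel = np.maximum(times_ms - spec.pulse_ms, 0.0)
            depth = spec.reset_strength * (1.0 - spec.background_suppression)
            suppression = depth * np.exp(-t_rel / spec.recovery_tau_ms)
            suppression[times_ms < spec.pulse_ms] = 0.0
        source_phase[e] = theta
        data[e] = _render_epoch(spec, geo, theta, labels, rng, evoked,
                                suppression=suppression)

    eeg = EpochedEEG(
        data=data,
        fs=spec.fs,
        channel_names=_channel_names(spec.n_channels),
        pulse_sample=pulse_idx if stimulated else 0,
        channel_positions=geo.channel_positions,
        subject_id=f"sub{subject:02d}",
    )
    eeg.planted = {
        "cluster_channels": [eeg.channel_names[i] for i in geo.cluster_channels],
        "cluster_channel_idx": geo.cluster_channels,
        "cluster_sources": geo.cluster_sources,
        "reset_sources": reset_subsets,
        "source_phase": source_phase,
        "templates": geo.templates,
        "evoked_profile": geo.evoked_profile,
        "mixing": geo.mixing,
        "omega": geo.omega,
    }
    return eeg


def generate_tms_epochs(spec: SyntheticCohortSpec, subject: int = 0) -> EpochedEEG:
    """Stimulated epochs for one subject (pulse at ``spec.pulse_ms``).

    The returned container carries a ``planted`` dict describing ground
    truth (cluster channels/sources, source phases, templates).
    """
    return _generate_epochs(spec, subject, stimulated=True)


def generate_resting_eeg(spec: SyntheticCohortSpec, subject: int = 0) -> EpochedEEG:
    """Unstimulated epochs with the same generative model (no pulse)."""
    return _generate_epochs(spec, subject, stimulated=False)


def generate_resting_record(spec: SyntheticCohortSpec, subject: int = 0,
                            duration_ms: float = 10_000.0) -> ContinuousEEG:
    """Continuous resting recording (for microstate fitting)."""
    geo = _subject_geometry(spec, subject)
    n_samp = int(round(duration_ms * spec.fs / 1000.0))
    rng = np.random.default_rng([spec.seed, subject, 9])
    theta = _run_sources(spec, geo.omega, rng, n_samp)
    labels = _dwell_labels(spec, rng, n_samp)
    data = _render_epoch(spec, geo, theta, labels, rng, evoked=None)
    rec = ContinuousEEG(
        data=data,
        fs=spec.fs,
        channel_names=_channel_names(spec.n_channels),
        channel_positions=geo.channel_positions,
        subject_id=f"sub{subject:02d}",
    )
    rec.planted = {"templates": geo.templates, "labels": labels}
    return rec
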