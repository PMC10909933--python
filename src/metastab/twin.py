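"""Delayed-Kuramoto connectome model with a propagating pulse phase reset.

Each node obeys
``dtheta_i/dt = omega_i + (K/N) sum_j c_ij sin(theta_j(t - tau_ij) - theta_i) + d zeta(t)``
integrated with Euler-Maruyama.  A simulated stimulation pulse forces the
phase of the stimulated region to a fixed value instantly and of every
other node after its conduction delay to the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._kernels import delayed_kuramoto
from .containers import Connectome
from .phase import KOPTrace, MetastabilityTrace, kop, sliding_metastability

logger = logging.getLogger(__name__)

__all__ = [
    "TwinParams",
    "SimulationRun",
    "assign_frequencies",
    "simulate",
    "tune_working_point",
    "find_low_coherence_times",
    "segmented_metastability",
    "seed_average",
    "apply_tms_reset",
    "select_subgroup",
    "run_experiment",
]


@dataclass
class TwinParams:
    """Integration parameters.  Times in ms, frequencies in Hz."""

    omega: np.ndarray  #: intrinsic angular frequencies, rad/ms
    coupling: float  #: global coupling K
    noise_scale: float = 3.0  #: d in rad/sqrt(s), scales unit-variance white noise
    dt: float = 0.1  #: integration step, ms
    duration_ms: float = 10_000.0
    seed: int = 0
    f_max: float | None = None
    f_spread: float | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")


@dataclass
class SimulationRun:
    """Phase time series theta[node, t] plus derived synchrony traces."""

    theta: np.ndarray  #: (n_nodes, n_times), wrapped phases
    dt: float
    params: TwinParams
    seed: int
    reset_times_ms: np.ndarray | None = None  #: per-node reset schedule
    pulse_time_ms: float | None = None
    _kop: tuple | None = field(default=None, repr=False)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.theta.shape[1]) * self.dt

    def kop_trace(self, nodes=None) -> KOPTrace:
        idx = slice(None) if nodes is None else np.asarray(nodes, dtype=np.intp)
        r, psi = kop(self.theta[idx, :], axis=0)
        fs = 1000.0 / self.dt
        labels = (
            [f"node{i}" for i in range(self.theta.shape[0])]
            if nodes is None
            else [f"node{i}" for i in np.atleast_1d(idx)]
        )
        return KOPTrace(r=r[None, :], psi=psi[None, :], channel_set=labels, fs=fs)

    def metastability(self, window_ms: float = 500.0, nodes=None) -> MetastabilityTrace:
        return sliding_metastability(self.kop_trace(nodes), window_ms=window_ms)


def assign_frequencies(strengths: np.ndarray, f_max: float, f_spread: float = 3.0
                       ) -> np.ndarray:
    """Map node strengths to intrinsic frequencies, strongest hubs slowest.

    ``f_i = f_max - f_spread * (s_i - s_min) / (s_max - s_min)`` (Hz);
    returns angular frequencies in rad/ms.  Shifting ``f_max`` translates
    every node's frequency equally, preserving the dispersion.
    """
    s = np.asarray(strengths, dtype=float)
    if (s < 0).any():
        raise ValueError("strengths must be nonnegative")
    rng_s = s.max() - s.min()
    if rng_s == 0:
        raise ValueError("all node strengths equal; frequency mapping undefined")
    f = f_max - f_spread * (s - s.min()) / rng_s
    return 2.0 * np.pi * f / 1000.0


def _lag_steps(connectome: Connectome, dt: float) -> np.ndarray:
    tau = connectome.delays
    off_diag = tau[~np.eye(tau.shape[0], dtype=bool)]
    pos = off_diag[off_diag > 0]
    if pos.size and dt > pos.min():
        raise ValueError(
            f"dt={dt} ms exceeds the smallest positive delay ({pos.min():.4g} ms)"
        )
    return np.rint(tau / dt).astype(np.int64)


def simulate(connectome: Connectome, params: TwinParams,
             reset_steps: np.ndarray | None = None,
             reset_value: float = np.pi / 2) -> SimulationRun:
    """Integrate the network; optionally force per-node phase resets.

    The pre-t=0 history is backfilled as ``theta_i(0) - omega_i * |t|``
    from a seeded uniform initial phase, so delayed couplings are defined
    from the first step.  A fixed seed gives bit-identical output.
    """
    n = connectome.n_nodes
    if params.omega.shape != (n,):
        raise ValueError("omega length must match the connectome")
    lags = _lag_steps(connectome, params.dt)
    n_hist = int(lags.max()) + 1
    n_steps = int(round(params.duration_ms / params.dt))

    rng = np.random.default_rng(params.seed)
    theta0 = rng.uniform(-np.pi, np.pi, size=n)
    noise = rng.standard_normal((n_steps, n))

    theta = np.empty((n_hist + n_steps, n))
    back = np.arange(n_hist - 1, -1, -1, dtype=float) * params.dt
    theta[:n_hist] = theta0[None, :] - params.omega[None, :] * back[:, None]
    theta[:n_hist] = (theta[:n_hist] + np.pi) % (2 * np.pi) - np.pi

    if reset_steps is None:
        reset_steps = np.full(n, -1, dtype=np.int64)
    delayed_kuramoto(
        theta, params.omega, connectome.weights, lags, params.coupling,
        params.dt, np.sqrt(params.dt / 1000.0) * params.noise_scale, noise,
        n_hist, np.asarray(reset_steps, dtype=np.int64), reset_value,
    )
    out = theta[n_hist - 1 :].T  # (n, n_steps + 1), t = 0 .. duration
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite phases during integration")
    reset_ms = None
    if (np.asarray(reset_steps) >= 0).any():
        reset_ms = np.where(reset_steps >= 0, reset_steps * params.dt, np.nan)
    return SimulationRun(theta=out, dt=params.dt, params=params,
                         seed=params.seed, reset_times_ms=reset_ms)


def find_low_coherence_times(r: np.ndarray, dt: float, burn_in_ms: float = 2000.0,
                             smooth_ms: float = 25.0,
                             prominence_factor: float = 0.5) -> np.ndarray:
    """Times (ms) of low-coherence troughs of a smoothed KOP trace.

    Local minima of the 25 ms moving-average of r, after burn-in, with
    prominence at least ``prominence_factor`` times the trace std.
    """
    r = np.asarray(r, dtype=float).ravel()
    w = max(int(round(smooth_ms / dt)), 1)
    if w > r.size:
        raise ValueError("smoothing window longer than trace")
    smooth = np.convolve(r, np.ones(w) / w, mode="same")
    start = int(round(burn_in_ms / dt))
    if start >= r.size:
        raise ValueError("burn-in longer than trace")
    seg = smooth[start:]
    prom = prominence_factor * seg.std()
    minima, _ = find_peaks(-seg, prominence=prom)
    if minima.size == 0:
        raise ValueError(
            "no low-coherence troughs found; run longer or lower the prominence"
        )
    return (start + minima) * dt


def apply_tms_reset(connectome: Connectome, params: TwinParams, pulse_time_ms: float,
                    site_node: int, instant_radius_mm: float = 20.0,
                    reset_value: float = np.pi / 2) -> SimulationRun:
    """Re-run a simulation with a propagating phase reset at ``pulse_time_ms``.

    Nodes within ``instant_radius_mm`` of the site (Euclidean, a stand-in
    for the stimulated-field region) reset at the pulse; every other node
    resets at ``pulse + tau(i, site)``.  The same seed reproduces the
    pre-pulse trajectory of the unperturbed run exactly.
    """
    n = connectome.n_nodes
    if not 0 <= site_node < n:
        raise ValueError(f"site_node {site_node} out of range")
    dist_to_site = np.linalg.norm(
        connectome.coordinates - connectome.coordinates[site_node], axis=1
    )
    instant = dist_to_site <= instant_radius_mm
    instant[site_node] = True
    delay_ms = np.where(instant, 0.0, connectome.delays[:, site_node])
    reset_steps = np.rint((pulse_time_ms + delay_ms) / params.dt).astype(np.int64)
    run = simulate(connectome, params, reset_steps=reset_steps,
                   reset_value=reset_value)
    run.pulse_time_ms = pulse_time_ms
    return run


def select_subgroup(omega: np.ndarray, target_node: int, tolerance_hz: float = 1.0
                    ) -> np.ndarray:
    """Indices of nodes whose intrinsic frequency is near the target's."""
    omega = np.asarray(omega, dtype=float)
    if not 0 <= target_node < omega.size:
        raise ValueError("target node out of range")
    f = omega * 1000.0 / (2.0 * np.pi)
    sel = np.abs(f - f[target_node]) <= tolerance_hz
    sel[target_node] = True
    return np.flatnonzero(sel)


def tune_working_point(connectome: Connectome, k_grid, velocity_grid,
                       base_params: TwinParams, f_max: float = 15.0,
                       f_spread: float = 3.0, window_ms: float = 500.0,
                       burn_in_ms: float = 1000.0):
    """Grid search (K, conduction velocity) maximizing mean windowed KOP std.

    Returns ``((K*, v*), table)`` where the table holds the metastability
    score of every grid cell.
    """
    k_grid = list(k_grid)
    velocity_grid = list(velocity_grid)
    if not k_grid or not velocity_grid:
        raise ValueError("empty parameter grid")
    rows = []
    burn = int(round(burn_in_ms / base_params.dt))
    for v in velocity_grid:
        delays = connectome.distances / v
        conn_v = Connectome(
            weights=connectome.weights, distances=connectome.distances,
            delays=delays, coordinates=connectome.coordinates,
            node_labels=list(connectome.node_labels),
        )
        omega = assign_frequencies(conn_v.strengths, f_max, f_spread)
        for k in k_grid:
            params = replace(base_params, omega=omega, coupling=k)
            run = simulate(conn_v, params)
            meta = run.metastability(window_ms=window_ms)
            score = float(np.nanmean(meta.value[..., burn:]))
            r_mean = float(run.kop_trace().r[..., burn:].mean())
            rows.append(dict(K=k, velocity=v, score=score, mean_r=r_mean))
    table = pd.DataFrame(rows)
    if table["score"].max() - table["score"].min() < 1e-6:
        logger.warning("all grid cells nearly degenerate; working point ill-defined")
    best = table.loc[table["score"].idxmax()]
    return (float(best["K"]), float(best["velocity"])), table


def segmented_metastability(r: np.ndarray, pulse_index: int, window: int,
                            min_support: int | None = None,
                            transient: int = 0) -> np.ndarray:
    """Windowed population std of r with the pulse treated as a boundary.

    No window mixes pre-pulse samples with post-pulse ones (the forced
    discontinuity would otherwise dominate the std for half a window
    length on either side).  ``transient`` extends the boundary to cover
    the reset-propagation interval ``[pulse, pulse + transient]``, which
    is excluded from every window; centers inside it are NaN.  Windows
    are clipped at the boundary; positions with fewer than
    ``min_support`` samples (default half window) are NaN.
    """
    r = np.asarray(r, dtype=float).ravel()
    n = r.size
    if min_support is None:
        min_support = window // 2
    left = (window - 1) // 2
    right = window // 2
    b0 = pulse_index
    b1 = min(pulse_index + transient, n)
    c1 = np.concatenate([[0.0], np.cumsum(r)])
    c2 = np.concatenate([[0.0], np.cumsum(r**2)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)  # exclusive
    pre = idx < b0
    post = idx >= b1
    lo = np.where(pre, lo, np.maximum(lo, b1))
    hi = np.where(pre, np.minimum(hi, b0), hi)
    cnt = np.maximum(hi - lo, 0)
    ok = (cnt >= min_support) & (pre | post)
    cnt_safe = np.maximum(cnt, 1)
    mean = (c1[hi] - c1[lo]) / cnt_safe
    var = (c2[hi] - c2[lo]) / cnt_safe - mean**2
    out = np.sqrt(np.maximum(var, 0.0))
    out[~ok] = np.nan
    return out


def seed_average(stack) -> np.ndarray:
    """Mean across seeds, exactly invariant to seed order.

    Values are sorted per time point before summation, fixing the
    floating-point accumulation order; NaNs (window margins) are ignored.
    """
    arr = np.sort(np.asarray(stack, dtype=float), axis=0)  # NaN sorts last
    with np.errstate(invalid="ignore"):
        return np.nanmean(arr, axis=0)


def _recovery_time(meta_mean: np.ndarray, times: np.ndarray, pulse_ms: float,
                   baseline_window_ms: tuple[float, float] = (-1500.0, -100.0),
                   search_ms: float = 3000.0, dip_window_ms: float = 800.0) -> float:
    """First post-dip time the trace re-enters the +/-1 SD baseline band.

    The dip is the minimum within ``dip_window_ms`` after the pulse (the
    suppression trough); later secondary fluctuations are not treated as
    the stimulus response.
    """
    rel = times - pulse_ms
    base_mask = (rel >= baseline_window_ms[0]) & (rel <= baseline_window_ms[1])
    base = meta_mean[base_mask]
    mu, sd = np.nanmean(base), np.nanstd(base)
    post = (rel > 0) & (rel <= search_ms)
    seg = meta_mean[post]
    seg_t = rel[post]
    if seg.size == 0 or np.isnan(seg).all():
        return np.nan
    early = np.where(seg_t <= dip_window_ms, seg, np.inf)
    if not np.isfinite(early).any():
        return np.nan
    dip = int(np.nanargmin(early))
    inside = seg[dip:] >= mu - sd
    hits = np.flatnonzero(inside)
    if hits.size == 0:
        return np.nan
    return float(seg_t[dip + hits[0]])


def run_experiment(connectome: Connectome, base_params: TwinParams,
                   site_node: int, f_max_list=(5.0, 15.0, 25.0, 35.0),
                   f_spread: float = 3.0, n_seeds: int = 20,
                   subgroup_tolerance_hz: float = 1.0,
                   instant_radius_mm: float = 20.0,
                   window_ms: float = 500.0, burn_in_ms: float = 2000.0,
                   align_pre_ms: float = 2000.0, align_post_ms: float = 3000.0,
                   trough_search_ms: float = 2500.0, seed_start: int = 0):
    """Pulse-aligned, seed-averaged subgroup KOP and metastability per f_max.

    For every (f_max, seed): simulate unperturbed, pick the first
    low-coherence trough after burn-in, re-run with the propagating
    reset (same seed, so the pre-pulse trajectory is identical), then
    extract subgroup traces aligned to the pulse.  The windowed std is
    computed with the pulse as a segment boundary (see
    :func:`segmented_metastability`) so the forced discontinuity does not
    masquerade as variability.  Failing seeds are logged and excluded.
    """
    i_pre = int(round(align_pre_ms / base_params.dt))
    i_post = int(round(align_post_ms / base_params.dt))
    w = int(round(window_ms / base_params.dt))
    free_duration = max(burn_in_ms, align_pre_ms) + trough_search_ms
    results = {}
    for f_max in f_max_list:
        omega = assign_frequencies(connectome.strengths, f_max, f_spread)
        subgroup = select_subgroup(omega, site_node, subgroup_tolerance_hz)
        kop_stack, meta_stack = [], []
        for seed in range(seed_start, seed_start + n_seeds):
            try:
                params = replace(base_params, omega=omega, seed=seed,
                                 duration_ms=free_duration,
                                 f_max=f_max, f_spread=f_spread)
                free = simulate(connectome, params)
                r_free = free.kop_trace().r[0]
                pulse_candidates = find_low_coherence_times(
                    r_free, params.dt, burn_in_ms=max(burn_in_ms, align_pre_ms)
                )
                if pulse_candidates.size == 0:
                    raise ValueError("no usable trough in the search window")
                pulse_ms = float(pulse_candidates[0])
                full = replace(params, duration_ms=pulse_ms + align_post_ms)
                run = apply_tms_reset(connectome, full, pulse_ms, site_node,
                                      instant_radius_mm=instant_radius_mm)
                r_sub = run.kop_trace(nodes=subgroup).r[0]
                i_pulse = int(round(pulse_ms / params.dt))
                transient = int(np.ceil(
                    (np.nanmax(run.reset_times_ms) - pulse_ms) / params.dt
                ))
                meta = segmented_metastability(r_sub, i_pulse, w,
                                               transient=transient)
                kop_stack.append(r_sub[i_pulse - i_pre : i_pulse + i_post + 1])
                meta_stack.append(meta[i_pulse - i_pre : i_pulse + i_post + 1])
            except (ValueError, FloatingPointError) as exc:
                logger.warning("f_max=%s seed %d failed: %s", f_max, seed, exc)
        if not kop_stack:
            raise RuntimeError(f"every seed failed for f_max={f_max}")
        times_rel = (np.arange(-i_pre, i_post + 1)) * base_params.dt
        kop_mean = seed_average(kop_stack)
        meta_mean = seed_average(meta_stack)
        results[f_max] = dict(
            times_ms=times_rel,
            kop_mean=kop_mean,
            meta_mean=meta_mean,
            kop_all=np.asarray(kop_stack),
            meta_all=np.asarray(meta_stack),
            n=len(kop_stack),
            subgroup=subgroup,
            recovery_ms=_recovery_time(meta_mean, times_rel, 0.0),
        )
    return results
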