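"""Numerical kernels for the delayed Kuramoto integrator."""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def delayed_kuramoto(theta, omega, weights, lags, coupling_k, dt, noise_amp,
                     noise, n_hist, reset_steps, reset_value):
    """Euler-Maruyama integration of a delay-coupled phase network.

    theta : (n_hist + n_steps, n) work array; rows [0, n_hist) hold the
        pre-t0 history, row n_hist - 1 is the t=0 state.  Filled in place.
    lags : (n, n) integer delay in steps for the coupling theta_j(t - tau_ij).
    noise : (n_steps, n) standard-normal draws; scaled by noise_amp
        (= sqrt(dt) * d).
    reset_steps : (n,) step index at which node i's phase is forced to
        reset_value (-1 disables).
    """
    n = theta.shape[1]
    n_steps = noise.shape[0]
    two_pi = 2.0 * np.pi
    for step in range(n_steps):
        g = n_hist - 1 + step
        for i in range(n):
            if reset_steps[i] == step:
                theta[g, i] = reset_value
        for i in range(n):
            acc = 0.0
            th_i = theta[g, i]
            for j in range(n):
                w = weights[i, j]
                if w != 0.0:
                    acc += w * np.sin(theta[g - lags[i, j], j] - th_i)
            val = th_i + dt * (omega[i] + (coupling_k / n) * acc) \
                + noise_amp * noise[step, i]
            val = (val + np.pi) % two_pi - np.pi
            theta[g + 1, i] = val
    # a reset scheduled exactly at the final step still lands in the output
    for i in range(n):
        if reset_steps[i] == n_steps:
            theta[n_hist - 1 + n_steps, i] = reset_value
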