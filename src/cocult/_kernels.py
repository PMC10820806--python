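"""Numba-accelerated Euler kernels.

These replicate the numpy batch kernels in :mod:`cocult.solver` operation for
operation (same update order, same clamping), so results are bit-identical;
a test asserts that equivalence.  When numba is unavailable the package
falls back to the numpy kernels transparently.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(cache=True)
def direct_kernel(
    params,  # (m, 6) float64: rho_W, rho_P, k_WW, k_WP, k_PW, k_PP
    switched,  # (m, 6) float64; read only when switch_step >= 0
    switch_step,  # int64; -1 for no intervention
    W0,  # (m, n) float64
    P0,
    dt,
    n_steps,
    sample_steps,  # (ns,) int64, strictly increasing
):
    m, n = W0.shape
    ns = sample_steps.shape[0]
    out_W = np.empty((ns, m, n))
    out_P = np.empty((ns, m, n))
    for i in range(m):
        rho_W0 = params[i, 0]
        rho_P0 = params[i, 1]
        k_WW0 = params[i, 2]
        k_WP0 = params[i, 3]
        k_PW0 = params[i, 4]
        k_PP0 = params[i, 5]
        for j in range(n):
            W = W0[i, j]
            P = P0[i, j]
            rho_W, rho_P = rho_W0, rho_P0
            k_WW, k_WP, k_PW, k_PP = k_WW0, k_WP0, k_PW0, k_PP0
            si = 0
            for step in range(n_steps + 1):
                if si < ns and step == sample_steps[si]:
                    out_W[si, i, j] = W
                    out_P[si, i, j] = P
                    si += 1
                if step == n_steps:
                    break
                if switch_step >= 0 and step >= switch_step:
                    rho_W = switched[i, 0]
                    rho_P = switched[i, 1]
                    k_WW = switched[i, 2]
                    k_WP = switched[i, 3]
                    k_PW = switched[i, 4]
                    k_PP = switched[i, 5]
                dW = W * (rho_W - k_WW * W - k_WP * P)
                dP = P * (rho_P - k_PP * P - k_PW * W)
                W = W + dt * dW
                P = P + dt * dP
                if W < 0.0:
                    W = 0.0
                if P < 0.0:
                    P = 0.0
    return out_W, out_P


@njit(cache=True)
def resource_kernel(
    params,  # (m, 8): alpha_W, alpha_P, delta_W, delta_P, gamma_W, gamma_P, r_W, r_P
    W0,  # (m, n)
    P0,
    R0,  # (m, n)
    dt,
    n_steps,
    sample_steps,
):
    m, n = W0.shape
    ns = sample_steps.shape[0]
    out_W = np.empty((ns, m, n))
    out_P = np.empty((ns, m, n))
    out_R = np.empty((ns, m, n))
    for i in range(m):
        alpha_W = params[i, 0]
        alpha_P = params[i, 1]
        delta_W = params[i, 2]
        delta_P = params[i, 3]
        gamma_W = params[i, 4]
        gamma_P = params[i, 5]
        r_W = params[i, 6]
        r_P = params[i, 7]
        for j in range(n):
            W = W0[i, j]
            P = P0[i, j]
            R = R0[i, j]
            si = 0
            for step in range(n_steps + 1):
                if si < ns and step == sample_steps[si]:
                    out_W[si, i, j] = W
                    out_P[si, i, j] = P
                    out_R[si, i, j] = R
                    si += 1
                if step == n_steps:
                    break
                sW = 1.0 if R < r_W else 0.0
                sP = 1.0 if R < r_P else 0.0
                dW = W * (alpha_W - delta_W * sW)
                dP = P * (alpha_P - delta_P * sP)
                dR = -(gamma_W * W + gamma_P * P) * (1.0 if R > 0.0 else 0.0)
                W = W + dt * dW
                P = P + dt * dP
                R = R + dt * dR
                if W < 0.0:
                    W = 0.0
                if P < 0.0:
                    P = 0.0
                if R < 0.0:
                    R = 0.0
    return out_W, out_P, out_R
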