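"""Numba kernels for the mean-field self-consistency equations.

This module holds the numerical core shared by every public mean-field
routine: the scaled complementary error function, the saturating NMDA
activation series, the first-passage-time transfer function and the
forward-Euler relaxation loop.  The public API in
:mod:`wagernet.meanfield` wraps these kernels; keeping a single
implementation avoids drift between the flow used for fixed points and
the functions exposed for inspection.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)

# Upper-bound cutoff: beyond this the transfer integral is so large the
# rate is numerically zero.
ALPHA_CUTOFF = 12.0


@njit(cache=True)
def erfcx_nb(x: float) -> float:
    """exp(x^2) * erfc(x), stable for any argument met in the flow."""
    if x < 0.0:
        # erfcx(-a) = 2 exp(a^2) - erfcx(a); |x| <= ALPHA_CUTOFF here.
        return 2.0 * math.exp(x * x) - erfcx_nb(-x)
    if x < 25.0:
        return math.exp(x * x) * math.erfc(x)
    # Asymptotic series 1/(x sqrt(pi)) * sum (-1)^n (2n-1)!! / (2 x^2)^n
    ix2 = 1.0 / (2.0 * x * x)
    s = 1.0
    term = 1.0
    for n in range(1, 9):
        term *= -(2 * n - 1) * ix2
        s += term
    return s / (x * SQRT_PI)


@njit(cache=True)
def psi_nb(nu_ms: float, tau_rise: float, tau_decay: float,
           tau_nmda: float, alpha: float) -> float:
    """Stationary NMDA gating for presynaptic rate ``nu_ms`` (ms^-1)."""
    tn = nu_ms * tau_nmda
    x = tau_rise * (1.0 + tn) / tau_decay
    base = -alpha * tau_rise
    series = 0.0
    term = 1.0
    for n in range(1, 65):
        term = term * base / (x + n)
        contrib = term / (n + 1)
        series += contrib
        if abs(contrib) < 1e-12:
            break
    return tn / (1.0 + tn) * (1.0 + series / (1.0 + tn))


@njit(cache=True)
def transfer_nb(mu: float, sigma: float, tau_x: float, tau_rp: float,
                tau_ampa: float, v_thr: float, v_reset: float,
                nodes: np.ndarray, weights: np.ndarray) -> float:
    """Population rate (Hz) from the first-passage-time formula."""
    k = tau_ampa / tau_x
    a = (v_thr - mu) / sigma * (1.0 + 0.5 * k) + 1.03 * math.sqrt(k) - 0.5 * k
    b = (v_reset - mu) / sigma
    if a > ALPHA_CUTOFF:
        return 0.0
    if a <= b:
        # mean drive far above threshold: the first-passage integral
        # vanishes and the rate saturates at the refractory ceiling
        return 1e3 / tau_rp
    half = 0.5 * (a - b)
    mid = 0.5 * (a + b)
    integral = 0.0
    for i in range(nodes.shape[0]):
        u = mid + half * nodes[i]
        integral += weights[i] * erfcx_nb(-u)
    integral *= half * SQRT_PI
    return 1e3 / (tau_rp + tau_x * integral)


@njit(cache=True)
def mf_eval(nu, v_avg, lam,
            r, W, g_m, C_m, tau_m, tau_rp, g_ext, T_ext, T_AMPA, T_I, gN,
            tau_ampa, tau_rise, tau_decay, tau_nmda, alpha, beta, gamma,
            V_E, V_I, V_L, v_thr, v_reset, nu_ext,
            mu, sigma, tau_eff, S_out):
    """One evaluation of mu, sigma, tau and S for all 5 populations.

    ``nu`` in Hz; outputs written into the preallocated arrays.
    Returns False if the effective conductance becomes non-positive.
    """
    # Drives (rates in ms^-1).
    n_ampa = np.zeros(5)
    n_nmda = np.zeros(5)
    n_gaba = np.zeros(5)
    for x in range(5):
        sa = 0.0
        sn = 0.0
        for j in range(4):
            sa += r[j] * W[j, x] * (nu[j] * 1e-3)
            sn += r[j] * W[j, x] * psi_nb(nu[j] * 1e-3, tau_rise, tau_decay,
                                          tau_nmda, alpha)
        n_ampa[x] = sa
        n_nmda[x] = sn
        n_gaba[x] = W[4, x] * (nu[4] * 1e-3)

    for x in range(5):
        next_x = (nu_ext + lam[x]) * 1e-3
        J = 1.0 + gamma * math.exp(-beta * v_avg[x])
        rho1 = gN[x] / J
        rho2 = beta * gN[x] * (v_avg[x] - V_E) * (J - 1.0) / (J * J)
        S = (1.0 + T_ext[x] * next_x + T_AMPA[x] * n_ampa[x]
             + (rho1 + rho2) * n_nmda[x] + T_I[x] * n_gaba[x])
        if S <= 0.0:
            return False
        S_out[x] = S
        mu[x] = ((T_ext[x] * next_x + T_AMPA[x] * n_ampa[x] + rho1 * n_nmda[x]) * V_E
                 + rho2 * n_nmda[x] * v_avg[x]
                 + T_I[x] * n_gaba[x] * V_I + V_L) / S
        tau_eff[x] = C_m[x] * 1e3 / (g_m[x] * S)
        sig2 = (g_ext[x] * g_ext[x] * (v_avg[x] - V_E) * (v_avg[x] - V_E)
                * next_x * tau_ampa * tau_ampa * tau_eff[x]
                / (g_m[x] * g_m[x] * tau_m[x] * tau_m[x]))
        sigma[x] = math.sqrt(sig2)
    return True


@njit(cache=True)
def mf_solve(nu0, v_avg0, lam,
             r, W, g_m, C_m, tau_m, tau_rp, g_ext, T_ext, T_AMPA, T_I, gN,
             tau_ampa, tau_rise, tau_decay, tau_nmda, alpha, beta, gamma,
             V_E, V_I, V_L, v_thr, v_reset, nu_ext,
             nodes, gl_weights, dt, tol, max_steps):
    """Euler relaxation of the self-consistency flow.

    Returns (nu, v_avg, steps, status): status 1 = converged,
    0 = step budget exhausted, -1 = numerical failure.
    """
    nu = nu0.copy()
    v_avg = v_avg0.copy()
    mu = np.zeros(5)
    sigma = np.zeros(5)
    tau_eff = np.zeros(5)
    S_out = np.zeros(5)
    steps = 0
    for steps in range(1, max_steps + 1):
        ok = mf_eval(nu, v_avg, lam, r, W, g_m, C_m, tau_m, tau_rp, g_ext,
                     T_ext, T_AMPA, T_I, gN, tau_ampa, tau_rise, tau_decay,
                     tau_nmda, alpha, beta, gamma, V_E, V_I, V_L,
                     v_thr, v_reset, nu_ext, mu, sigma, tau_eff, S_out)
        if not ok:
            return nu, v_avg, steps, -1
        max_d = 0.0
        for x in range(5):
            p = transfer_nb(mu[x], sigma[x], tau_eff[x], tau_rp[x],
                            tau_ampa, v_thr, v_reset, nodes, gl_weights)
            d = dt / tau_eff[x] * (p - nu[x])
            nu[x] += d
            if nu[x] < 0.0:
                nu[x] = 0.0
            if not math.isfinite(nu[x]):
                return nu, v_avg, steps, -1
            v_avg[x] = mu[x] - (v_thr - v_reset) * (nu[x] * 1e-3) * tau_eff[x]
            ad = abs(d)
            if ad > max_d:
                max_d = ad
        if max_d < tol:
            return nu, v_avg, steps, 1
    return nu, v_avg, max_steps, 0
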