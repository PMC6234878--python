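"""Compiled kernels for state-dependent speciation–extinction likelihoods.

Per-branch integration of the coupled MuSSE ODE system

    dE_i/dt = mu_i - (lam_i + mu_i + sum_j q_ij) E_i + sum_j q_ij E_j + lam_i E_i^2
    dD_i/dt =      - (lam_i + mu_i + sum_j q_ij) D_i + sum_j q_ij D_j + 2 lam_i E_i D_i

with an adaptive Cash–Karp Runge–Kutta 4(5) stepper, plus the postorder
tree recursion with per-node rescaling of D.
"""

import numpy as np
from numba import njit

__all__ = ["musse_root"]


@njit(cache=True)
def _deriv(y, k, lam, mu, Q, out):
    for i in range(k):
        qi = 0.0
        qE = 0.0
        qD = 0.0
        for j in range(k):
            if j != i:
                qi += Q[i, j]
                qE += Q[i, j] * y[j]
                qD += Q[i, j] * y[k + j]
        r = lam[i] + mu[i] + qi
        E = y[i]
        D = y[k + i]
        out[i] = mu[i] - r * E + qE + lam[i] * E * E
        out[k + i] = -r * D + qD + 2.0 * lam[i] * E * D


@njit(cache=True)
def _integrate_branch(y, t, k, lam, mu, Q, rtol, atol):
    """Advance (E, D) along a branch of length t in place; 0 = ok, 1 = fail."""
    if t <= 0.0:
        return 0
    n = 2 * k
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); k5 = np.empty(n); k6 = np.empty(n)
    ytmp = np.empty(n)
    y5 = np.empty(n)
    maxr = 0.0
    for i in range(k):
        qi = 0.0
        for j in range(k):
            if j != i:
                qi += Q[i, j]
        r = lam[i] + mu[i] + qi
        if r > maxr:
            maxr = r
    h = t if t * (1.0 + maxr) < 1.0 else 1.0 / (1.0 + maxr)
    s = 0.0
    for _ in range(1_000_000):
        if s >= t:
            return 0
        if s + h > t:
            h = t - s
        _deriv(y, k, lam, mu, Q, k1)
        for i in range(n):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, k, lam, mu, Q, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, k, lam, mu, Q, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, k, lam, mu, Q, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                -11.0 / 54.0 * k1[i] + 2.5 * k2[i]
                - 70.0 / 27.0 * k3[i] + 35.0 / 27.0 * k4[i]
            )
        _deriv(ytmp, k, lam, mu, Q, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                1631.0 / 55296.0 * k1[i] + 175.0 / 512.0 * k2[i]
                + 575.0 / 13824.0 * k3[i] + 44275.0 / 110592.0 * k4[i]
                + 253.0 / 4096.0 * k5[i]
            )
        _deriv(ytmp, k, lam, mu, Q, k6)
        errmax = 0.0
        for i in range(n):
            y5[i] = y[i] + h * (
                37.0 / 378.0 * k1[i] + 250.0 / 621.0 * k3[i]
                + 125.0 / 594.0 * k4[i] + 512.0 / 1771.0 * k6[i]
            )
            y4 = y[i] + h * (
                2825.0 / 27648.0 * k1[i] + 18575.0 / 48384.0 * k3[i]
                + 13525.0 / 55296.0 * k4[i] + 277.0 / 14336.0 * k5[i]
                + 0.25 * k6[i]
            )
            sc = atol + rtol * (abs(y[i]) if abs(y[i]) > abs(y5[i]) else abs(y5[i]))
            e = abs(y5[i] - y4) / sc
            if e > errmax:
                errmax = e
        if errmax <= 1.0:
            s += h
            for i in range(n):
                y[i] = y5[i]
            fac = 5.0 if errmax < 1e-4 else 0.9 * errmax ** -0.2
            h *= fac if fac < 5.0 else 5.0
        else:
            fac = 0.9 * errmax ** -0.25
            h *= fac if fac > 0.1 else 0.1
        if not np.isfinite(errmax):
            return 1
    return 1


@njit(cache=True)
def musse_root(blen, child_ptr, child_idx, n_tips, tipstate, rho, lam, mu, Q,
               rtol, atol):
    """Postorder MuSSE recursion on a binary tree.

    Returns ``(y_root, logscale)`` with ``y_root[:k] = E``, ``y_root[k:] = D``
    (D rescaled; ``logscale`` accumulates the log rescale factors).
    ``logscale`` is ``-inf`` for impossible data and ``nan`` on integrator
    failure.
    """
    n_nodes = len(blen)
    k = len(lam)
    top = np.zeros((n_nodes, 2 * k))
    logscale = 0.0
    y = np.zeros(2 * k)
    for node in range(n_nodes):
        if node < n_tips:
            for i in range(k):
                y[i] = 1.0 - rho[i]
                y[k + i] = 0.0
            y[k + tipstate[node]] = rho[tipstate[node]]
        else:
            j = node - n_tips
            c0 = child_idx[child_ptr[j]]
            c1 = child_idx[child_ptr[j] + 1]
            s = 0.0
            for i in range(k):
                y[i] = top[c0, i]
                y[k + i] = lam[i] * top[c0, k + i] * top[c1, k + i]
                s += y[k + i]
            if s <= 0.0:
                return y, -np.inf
            for i in range(k):
                y[k + i] /= s
            logscale += np.log(s)
        if node == n_nodes - 1:
            return y, logscale
        status = _integrate_branch(y, blen[node], k, lam, mu, Q, rtol, atol)
        if status != 0:
            return y, np.nan
        for i in range(2 * k):
            top[node, i] = y[i]
    return y, np.nan
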