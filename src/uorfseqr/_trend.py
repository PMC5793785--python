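"""Numerical kernels for first-order Poisson trend filtering.

The peak-caller background model minimises, over log-rates theta,

    sum_i w_i * (exp(theta_i) - c_i * theta_i)  +  lam * sum_i |theta_{i+1} - theta_i|

i.e. the Poisson negative log-likelihood with a first-order (fused-lasso)
penalty on adjacent differences of the log-rate, with 0/1 weights w used
to drop outlier positions from the fit. The problem is convex; it is
solved by ADMM where the smooth subproblem separates per coordinate
(Newton steps) and the penalty subproblem is an exact 1D total-variation
proximal step (Condat's direct, non-iterative algorithm).
"""

from __future__ import annotations

import numpy as np
from numba import njit

THETA_MIN = -30.0  # rate floor exp(-30) ~ 1e-13, numerically zero
THETA_MAX = 30.0


@njit(cache=False)
def tv1d_denoise(y, lam):
    """Exact prox of lam*TV: argmin_x 0.5*||x - y||^2 + lam*sum|x_{i+1}-x_i|."""
    n = y.size
    x = np.empty(n)
    if n == 0:
        return x
    if lam <= 0.0 or n == 1:
        x[:] = y
        return x
    k = 0
    k0 = 0
    kminus = 0
    kplus = 0
    umin = lam
    umax = -lam
    vmin = y[0] - lam
    vmax = y[0] + lam
    twolam = 2.0 * lam
    while True:
        while k == n - 1:
            if umin < 0.0:
                while True:
                    x[k0] = vmin
                    k0 += 1
                    if k0 > kminus:
                        break
                k = k0
                kminus = k
                vmin = y[kminus]
                umin = lam
                umax = vmin + lam - vmax
            elif umax > 0.0:
                while True:
                    x[k0] = vmax
                    k0 += 1
                    if k0 > kplus:
                        break
                k = k0
                kplus = k
                vmax = y[kplus]
                umax = -lam
                umin = vmax - lam - vmin
            else:
                vmin += umin / (k - k0 + 1)
                for i in range(k0, k + 1):
                    x[i] = vmin
                return x
        umin_new = umin + y[k + 1] - vmin
        umax_new = umax + y[k + 1] - vmax
        if umin_new < -lam:
            while True:
                x[k0] = vmin
                k0 += 1
                if k0 > kminus:
                    break
            k = k0
            kminus = k
            kplus = k
            vmin = y[k]
            vmax = y[k] + twolam
            umin = lam
            umax = -lam
        elif umax_new > lam:
            while True:
                x[k0] = vmax
                k0 += 1
                if k0 > kplus:
                    break
            k = k0
            kminus = k
            kplus = k
            vmin = y[k] - twolam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:
            k += 1
            umin = umin_new
            umax = umax_new
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


@njit(cache=False)
def poisson_trend_admm(counts, weights, lam, rho, max_iter, tol):
    """ADMM solve of the weighted Poisson trend-filter objective.

    Returns (rate, n_iterations); ``n_iterations == max_iter`` signals
    non-convergence at ``tol`` (caller may warn).
    """
    n = counts.size
    wsum = 0.0
    csum = 0.0
    for i in range(n):
        wsum += weights[i]
        csum += weights[i] * counts[i]
    theta = np.empty(n)
    if wsum > 0.0 and csum > 0.0:
        t0 = np.log(csum / wsum)
    else:
        t0 = THETA_MIN
    for i in range(n):
        theta[i] = t0
    z = theta.copy()
    u = np.zeros(n)
    it = 0
    while it < max_iter:
        it += 1
        # per-coordinate Newton on w*(e^t - c*t) + rho/2*(t - a)^2
        for i in range(n):
            a = z[i] - u[i]
            t = theta[i]
            w = weights[i]
            c = counts[i]
            for _ in range(60):
                e = np.exp(t)
                g = w * (e - c) + rho * (t - a)
                h = w * e + rho
                step = g / h
                t -= step
                if t < THETA_MIN:
                    t = THETA_MIN
                if t > THETA_MAX:
                    t = THETA_MAX
                if abs(step) < 1e-14:
                    break
            theta[i] = t
        znew = tv1d_denoise(theta + u, lam / rho)
        rmax = 0.0
        smax = 0.0
        for i in range(n):
            if znew[i] < THETA_MIN:
                znew[i] = THETA_MIN
            if znew[i] > THETA_MAX:
                znew[i] = THETA_MAX
            d1 = abs(theta[i] - znew[i])
            d2 = abs(znew[i] - z[i])
            if d1 > rmax:
                rmax = d1
            if d2 > smax:
                smax = d2
            u[i] += theta[i] - znew[i]
            z[i] = znew[i]
        if rmax < tol and smax < tol:
            break
    return np.exp(z), it
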