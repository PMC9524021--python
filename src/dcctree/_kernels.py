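"""Compiled recursions for GARCH(1,1) and bivariate DCC(1,1).

These inner loops run inside the quasi-likelihood objectives, which the
optimizer evaluates hundreds of times per fit and the calibration studies
call tens of thousands of times, hence numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def garch_filter(y: np.ndarray, omega: float, alpha: float, beta: float,
                 sigma2_init: float) -> np.ndarray:
    """Conditional-variance recursion s2[t] = omega + alpha*y[t-1]^2 + beta*s2[t-1]."""
    t_len = y.shape[0]
    sigma2 = np.empty(t_len)
    sigma2[0] = sigma2_init
    for t in range(1, t_len):
        sigma2[t] = omega + alpha * y[t - 1] * y[t - 1] + beta * sigma2[t - 1]
    return sigma2


@njit(cache=True)
def garch_nll(y: np.ndarray, omega: float, alpha: float, beta: float,
              sigma2_init: float) -> float:
    """Gaussian negative log-likelihood of the GARCH(1,1) recursion."""
    t_len = y.shape[0]
    s2 = sigma2_init
    nll = 0.5 * (_LOG_2PI + np.log(s2) + y[0] * y[0] / s2)
    for t in range(1, t_len):
        s2 = omega + alpha * y[t - 1] * y[t - 1] + beta * s2
        if s2 <= 0.0 or not np.isfinite(s2):
            return 1e12
        nll += 0.5 * (_LOG_2PI + np.log(s2) + y[t] * y[t] / s2)
    if not np.isfinite(nll):
        return 1e12
    return nll


@njit(cache=True)
def dcc_filter(e1: np.ndarray, e2: np.ndarray, theta1: float, theta2: float,
               q11bar: float, q12bar: float, q22bar: float) -> np.ndarray:
    """Correlation path r[t] from the DCC recursion, Q initialized at Q-bar."""
    t_len = e1.shape[0]
    r = np.empty(t_len)
    a = 1.0 - theta1 - theta2
    q11, q12, q22 = q11bar, q12bar, q22bar
    r[0] = q12 / np.sqrt(q11 * q22)
    for t in range(1, t_len):
        q11 = a * q11bar + theta1 * e1[t - 1] * e1[t - 1] + theta2 * q11
        q12 = a * q12bar + theta1 * e1[t - 1] * e2[t - 1] + theta2 * q12
        q22 = a * q22bar + theta1 * e2[t - 1] * e2[t - 1] + theta2 * q22
        r[t] = q12 / np.sqrt(q11 * q22)
    return r


@njit(cache=True)
def dcc_nll(e1: np.ndarray, e2: np.ndarray, theta1: float, theta2: float,
            q11bar: float, q12bar: float, q22bar: float) -> float:
    """Second-stage Gaussian quasi-likelihood of the correlation recursion.

    Terms constant in (theta1, theta2) are dropped.
    """
    t_len = e1.shape[0]
    a = 1.0 - theta1 - theta2
    q11, q12, q22 = q11bar, q12bar, q22bar
    nll = 0.0
    for t in range(t_len):
        if t > 0:
            q11 = a * q11bar + theta1 * e1[t - 1] * e1[t - 1] + theta2 * q11
            q12 = a * q12bar + theta1 * e1[t - 1] * e2[t - 1] + theta2 * q12
            q22 = a * q22bar + theta1 * e2[t - 1] * e2[t - 1] + theta2 * q22
        denom = q11 * q22
        if denom <= 0.0:
            return 1e12
        rho = q12 / np.sqrt(denom)
        one_m = 1.0 - rho * rho
        if one_m <= 1e-12:
            return 1e12
        x1, x2 = e1[t], e2[t]
        nll += 0.5 * (np.log(one_m)
                      + (x1 * x1 - 2.0 * rho * x1 * x2 + x2 * x2) / one_m)
    if not np.isfinite(nll):
        return 1e12
    return nll


@njit(cache=True)
def simulate_dcc_paths(z: np.ndarray, qbar: np.ndarray, theta1: float,
                       theta2: float, omega: np.ndarray, alpha: np.ndarray,
                       beta: np.ndarray, burn: int):
    """Draw an N-channel GARCH series whose innovations follow the DCC recursion.

    z : (N, burn+T) i.i.d. standard-normal draws.
    Returns (y, r_true) with y (N, T) and r_true (N, N, T) the realized
    conditional correlation matrices after burn-in.
    """
    n, total = z.shape
    t_len = total - burn
    q = qbar.copy()
    eps_prev = np.zeros(n)
    sigma2 = omega / (1.0 - alpha - beta)  # start at unconditional variance
    y_prev = np.sqrt(sigma2) * np.zeros(n)
    y = np.empty((n, t_len))
    r_true = np.empty((n, n, t_len))
    for t in range(total):
        if t > 0:
            outer = np.outer(eps_prev, eps_prev)
            q = (1.0 - theta1 - theta2) * qbar + theta1 * outer + theta2 * q
            for i in range(n):
                sigma2[i] = (omega[i] + alpha[i] * y_prev[i] * y_prev[i]
                             + beta[i] * sigma2[i])
        # rescale Q to the correlation matrix R_t
        d = np.empty(n)
        for i in range(n):
            d[i] = 1.0 / np.sqrt(q[i, i])
        r = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                r[i, j] = q[i, j] * d[i] * d[j]
        chol = np.linalg.cholesky(r)
        eps = chol @ np.ascontiguousarray(z[:, t])
        yt = np.sqrt(sigma2) * eps
        if t >= burn:
            k = t - burn
            y[:, k] = yt
            r_true[:, :, k] = r
        eps_prev = eps
        y_prev = yt
    return y, r_true
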