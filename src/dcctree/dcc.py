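"""Dynamic conditional correlation estimation for ROI pairs.

The model is the standard two-stage DCC(1,1)-GARCH(1,1):

stage 1 — each demeaned ROI series y_i gets a GARCH(1,1) conditional
variance  sigma2[t] = omega + alpha*y[t-1]^2 + beta*sigma2[t-1], fitted by
Gaussian quasi-maximum likelihood;

stage 2 — for each ROI pair the standardized residuals eps = y / sigma
drive the correlation recursion
Q_t = (1-theta1-theta2)*Qbar + theta1*eps_{t-1} eps_{t-1}' + theta2*Q_{t-1},
with Qbar the sample second-moment matrix of the residuals, and the dynamic
correlation R_t is Q_t rescaled to unit diagonal.  (theta1, theta2) are
fitted by the second-stage Gaussian quasi-likelihood under theta1, theta2
>= 0, theta1 + theta2 < 1.

Running this over all N(N-1)/2 pairs gives the N x N x T connectivity
tensor C_t whose (i, j, t) entry is the dynamic correlation between ROI i
and ROI j at time point t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .core_io import SubjectTimeSeries

logger = logging.getLogger(__name__)

_BOUNDARY_TOL = 1e-6
_DEFAULT_GARCH_STARTS = ((0.05, 0.90), (0.10, 0.80), (0.02, 0.50))
_DEFAULT_DCC_STARTS = ((0.05, 0.90), (0.02, 0.95), (0.10, 0.70))


class DegenerateSeriesError(ValueError):
    """Raised for constant / near-constant input series."""


@dataclass
class GarchFit:
    omega_hat: float
    alpha_hat: float
    beta_hat: float
    sigma_t: np.ndarray  # conditional standard deviations, length T
    loglik: float
    converged: bool

    @property
    def unconditional_variance(self) -> float:
        return self.omega_hat / (1.0 - self.alpha_hat - self.beta_hat)


@dataclass
class DccPairFit:
    theta1_hat: float
    theta2_hat: float
    qbar: np.ndarray  # 2x2
    r_t: np.ndarray  # length T, in [-1, 1]
    eps_t: np.ndarray  # 2xT standardized residuals
    loglik: float
    converged: bool
    boundary: bool = False


@dataclass
class DynamicConnectivity:
    """N x N x T tensor of dynamic correlations; symmetric, unit diagonal."""

    tensor: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or self.tensor.shape[0] != self.tensor.shape[1]:
            raise ValueError("connectivity tensor must be (N, N, T)")

    @property
    def n_rois(self) -> int:
        return self.tensor.shape[0]

    @property
    def t_len(self) -> int:
        return self.tensor.shape[2]


@dataclass
class FitReport:
    """Per-subject record of stage-1/stage-2 estimates and convergence flags."""

    subject_id: str
    garch: dict[int, GarchFit] = field(default_factory=dict)
    pair_converged: dict[tuple[int, int], bool] = field(default_factory=dict)
    pair_theta: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    fallback_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_fallback(self) -> int:
        return len(self.fallback_pairs)


def demean(series: np.ndarray) -> np.ndarray:
    """Mean-centre a 1-D series (or each row of a 2-D matrix)."""
    arr = np.asarray(series, dtype=float)
    if arr.shape[-1] < 2:
        raise ValueError("need at least 2 observations")
    return arr - arr.mean(axis=-1, keepdims=True)


def fit_garch(series: np.ndarray, starts: int = 3, tol: float = 1e-6) -> GarchFit:
    """Gaussian QMLE of GARCH(1,1) on a demeaned series.

    The variance recursion is initialized at the sample variance.  Multiple
    starting points guard against local optima; the best objective wins.
    Non-convergence of every start is flagged, never silently swallowed.
    """
    y = np.ascontiguousarray(series, dtype=float)
    if y.ndim != 1 or y.shape[0] < 50:
        raise ValueError("fit_garch needs a 1-D series with T >= 50")
    var = float(np.var(y))
    if var < 1e-12:
        raise DegenerateSeriesError("constant or near-constant series")

    def objective(params: np.ndarray) -> float:
        omega, alpha, beta = params
        if alpha + beta >= 1.0 - _BOUNDARY_TOL or omega <= 0:
            return 1e12
        return _kernels.garch_nll(y, omega, alpha, beta, var)

    best = None
    any_success = False
    for alpha0, beta0 in _DEFAULT_GARCH_STARTS[:starts]:
        x0 = np.array([var * (1.0 - alpha0 - beta0), alpha0, beta0])
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(1e-12 * max(var, 1.0), 10.0 * var), (0.0, 0.9999), (0.0, 0.9999)],
            options={"ftol": tol, "maxiter": 200},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    omega, alpha, beta = best.x
    sigma2 = _kernels.garch_filter(y, omega, alpha, beta, var)
    converged = bool(any_success and alpha + beta < 1.0 - _BOUNDARY_TOL
                     and np.isfinite(sigma2).all() and (sigma2 > 0).all())
    return GarchFit(
        omega_hat=float(omega), alpha_hat=float(alpha), beta_hat=float(beta),
        sigma_t=np.sqrt(sigma2), loglik=-float(best.fun), converged=converged,
    )


def standardized_residuals(pair: np.ndarray, fits: tuple[GarchFit, GarchFit]) -> np.ndarray:
    """eps[i, t] = y[i, t] / sigma[i, t] for a 2 x T pair."""
    pair = np.asarray(pair, dtype=float)
    if pair.shape[0] != 2:
        raise ValueError("pair must be 2 x T")
    sig = np.vstack([fits[0].sigma_t, fits[1].sigma_t])
    if (sig <= 0).any():
        raise ValueError("non-positive conditional standard deviation")
    return pair / sig


def _rescaled_qbar_offdiag(qbar: np.ndarray) -> float:
    return float(qbar[0, 1] / np.sqrt(qbar[0, 0] * qbar[1, 1]))


def fit_dcc_pair(
    eps: np.ndarray,
    starts: int = 3,
    tol: float = 1e-6,
    fixed_theta: tuple[float, float] | None = None,
) -> DccPairFit:
    """Second-stage QMLE of (theta1, theta2) for one pair of residual series.

    Qbar is the sample average of eps_t eps_t'; Q_1 is initialized at Qbar,
    which makes the theta1 = theta2 = 0 limit exactly the constant rescaled
    Qbar correlation.  Pass ``fixed_theta`` to skip estimation (e.g. (0, 0)
    for the static limit).
    """
    eps = np.ascontiguousarray(eps, dtype=float)
    if eps.ndim != 2 or eps.shape[0] != 2:
        raise ValueError("eps must be 2 x T")
    if not np.isfinite(eps).all():
        raise ValueError("non-finite residuals")
    t_len = eps.shape[1]
    if fixed_theta is None and t_len < 50:
        raise ValueError("fit_dcc_pair needs T >= 50")
    e1, e2 = np.ascontiguousarray(eps[0]), np.ascontiguousarray(eps[1])
    qbar = eps @ eps.T / t_len
    q11, q12, q22 = float(qbar[0, 0]), float(qbar[0, 1]), float(qbar[1, 1])

    if fixed_theta is not None:
        th1, th2 = fixed_theta
        r_t = _kernels.dcc_filter(e1, e2, th1, th2, q11, q12, q22)
        nll = _kernels.dcc_nll(e1, e2, th1, th2, q11, q12, q22)
        return DccPairFit(theta1_hat=th1, theta2_hat=th2, qbar=qbar, r_t=r_t,
                          eps_t=eps, loglik=-nll, converged=True,
                          boundary=th1 + th2 >= 1.0 - _BOUNDARY_TOL)

    def objective(params: np.ndarray) -> float:
        th1, th2 = params
        if th1 + th2 >= 1.0 - _BOUNDARY_TOL:
            return 1e12
        return _kernels.dcc_nll(e1, e2, th1, th2, q11, q12, q22)

    best = None
    any_success = False
    for x0 in _DEFAULT_DCC_STARTS[:starts]:
        res = minimize(
            objective, np.array(x0), method="L-BFGS-B",
            bounds=[(0.0, 0.9999), (0.0, 0.9999)],
            options={"ftol": tol, "maxiter": 200},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    th1, th2 = (float(v) for v in best.x)
    boundary = th1 + th2 >= 1.0 - 10 * _BOUNDARY_TOL
    r_t = _kernels.dcc_filter(e1, e2, th1, th2, q11, q12, q22)
    converged = bool(any_success and np.isfinite(r_t).all()
                     and (np.abs(r_t) <= 1.0).all())
    return DccPairFit(theta1_hat=th1, theta2_hat=th2, qbar=qbar, r_t=r_t,
                      eps_t=eps, loglik=-float(best.fun), converged=converged,
                      boundary=boundary)


def connectivity_tensor(
    ts: SubjectTimeSeries, starts: int = 3, tol: float = 1e-6
) -> tuple[DynamicConnectivity, FitReport]:
    """Estimate the full N x N x T dynamic-correlation tensor for one subject.

    One GARCH fit per ROI, then one pairwise DCC fit per ROI pair.  A ROI
    whose variance model cannot be fitted aborts the subject with the ROI
    named; a pair whose stage-2 fit fails falls back to its constant
    rescaled-Qbar correlation and is flagged in the report.
    """
    data = ts.data if ts.demeaned else demean(ts.data)
    n, t_len = data.shape
    report = FitReport(subject_id=ts.subject_id)
    sigmas = np.empty_like(data)
    for i in range(n):
        try:
            fit = fit_garch(data[i], starts=starts, tol=tol)
        except (DegenerateSeriesError, ValueError) as exc:
            raise RuntimeError(
                f"subject {ts.subject_id}: GARCH fit failed for ROI index {i + 1}: {exc}"
            ) from exc
        report.garch[i + 1] = fit
        sigmas[i] = fit.sigma_t
    eps_all = data / sigmas

    tensor = np.empty((n, n, t_len))
    tensor[np.arange(n), np.arange(n), :] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            eps = np.ascontiguousarray(eps_all[[i, j]])
            pair_fit = fit_dcc_pair(eps, starts=starts, tol=tol)
            if not pair_fit.converged:
                const = _rescaled_qbar_offdiag(pair_fit.qbar)
                logger.warning(
                    "subject %s pair (%d, %d): DCC fit failed; falling back to "
                    "constant correlation %.3f", ts.subject_id, i + 1, j + 1, const,
                )
                report.fallback_pairs.append((i + 1, j + 1))
                r_t = np.full(t_len, const)
            else:
                r_t = pair_fit.r_t
            report.pair_converged[(i + 1, j + 1)] = pair_fit.converged
            report.pair_theta[(i + 1, j + 1)] = (pair_fit.theta1_hat, pair_fit.theta2_hat)
            tensor[i, j, :] = r_t
            tensor[j, i, :] = r_t
    return DynamicConnectivity(tensor=tensor, subject_id=ts.subject_id), report
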