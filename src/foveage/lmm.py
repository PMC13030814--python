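"""Gaussian linear mixed model with a participant random intercept and an
optional penalized spline smooth, fitted by profiled maximum likelihood.

The model is

    y = X beta + Z_s b + Z_p u + e,
    b ~ N(0, sigma_b^2 I),  u ~ N(0, tau^2 I),  e ~ N(0, sigma^2 I),

where Z_p is the participant indicator matrix and Z_s an (optional)
truncated-power spline basis whose coefficients are shrunk as a variance
component — the classical mixed-model representation of a penalized
smooth, so the smoothing parameter is estimated by ML together with the
variance components and the smooth's effective degrees of freedom shrink
to the linear trend (edf -> 1) when the data carry no curvature.

beta and sigma^2 are profiled out: for given variance ratios
r_p = tau^2/sigma^2 and r_s = sigma_b^2/sigma^2 the GLS solution and the
ML sigma^2 are closed-form, leaving a 1- or 2-dimensional optimization
over log ratios.  Sample sizes here are a few hundred rows, so dense
Cholesky factorizations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["GaussianLMMFit", "fit_gaussian_lmm"]

_LOG_R_MIN, _LOG_R_MAX = -18.0, 8.0
_ZERO_RATIO = 1e-7     # below this a variance ratio is treated as zero


@dataclass
class GaussianLMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_resid: float       # residual SD
    sd_patient: float        # random-intercept SD
    sd_spline: float | None  # spline-coefficient SD (penalized smooth only)
    loglik: float            # ML log-likelihood
    aic: float
    n_params: int            # fixed effects + variance parameters
    edf_smooth: float | None  # effective df of the age smooth (spline fits)
    n_obs: int
    n_groups: int
    converged: bool


def _profile_nll(log_r: np.ndarray, y: np.ndarray, X: np.ndarray,
                 Zp: np.ndarray, Zs: np.ndarray | None) -> float:
    n = y.size
    V0 = np.eye(n) + np.exp(log_r[0]) * (Zp @ Zp.T)
    if Zs is not None:
        V0 += np.exp(log_r[1]) * (Zs @ Zs.T)
    try:
        c, low = linalg.cho_factor(V0, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Xw = linalg.cho_solve((c, low), X, check_finite=False)
    yw = linalg.cho_solve((c, low), y, check_finite=False)
    XtVX = X.T @ Xw
    beta = linalg.solve(XtVX, X.T @ yw, assume_a="pos")
    resid = y - X @ beta
    rss = float(resid @ linalg.cho_solve((c, low), resid, check_finite=False))
    sigma2 = rss / n
    if sigma2 <= 0:
        return 1e12
    return 0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)


def fit_gaussian_lmm(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray,
                     Zs: np.ndarray | None = None) -> GaussianLMMFit:
    """Fit by ML.  ``group_idx`` holds 0-based participant codes; ``Zs``
    is the penalized spline basis (or None for constant/linear fits)."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    m = int(group_idx.max()) + 1
    Zp = np.zeros((n, m))
    Zp[np.arange(n), group_idx] = 1.0

    k_var = 2 if Zs is None else 3          # sigma, tau (+ sigma_b)
    x0 = np.full(1 if Zs is None else 2, -1.0)
    res = optimize.minimize(
        _profile_nll, x0, args=(y, X, Zp, Zs), method="L-BFGS-B",
        bounds=[(_LOG_R_MIN, _LOG_R_MAX)] * x0.size)
    log_r = res.x
    r_p = float(np.exp(log_r[0]))
    r_s = float(np.exp(log_r[1])) if Zs is not None else 0.0
    if r_p < _ZERO_RATIO:
        r_p = 0.0
    if r_s < _ZERO_RATIO:
        r_s = 0.0

    V0 = np.eye(n) + r_p * (Zp @ Zp.T)
    if Zs is not None and r_s > 0:
        V0 += r_s * (Zs @ Zs.T)
    c, low = linalg.cho_factor(V0, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Xw = linalg.cho_solve((c, low), X, check_finite=False)
    yw = linalg.cho_solve((c, low), y, check_finite=False)
    XtVX = X.T @ Xw
    beta = linalg.solve(XtVX, X.T @ yw, assume_a="pos")
    resid = y - X @ beta
    sigma2 = float(resid @ linalg.cho_solve((c, low), resid,
                                            check_finite=False)) / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    cov_beta = sigma2 * linalg.inv(XtVX)

    edf_smooth = None
    if Zs is not None:
        # influence of [X, Z_s] under ridge 1/r_s on the spline block,
        # weighted by the participant-only covariance
        Vp = np.eye(n) + r_p * (Zp @ Zp.T)
        cp, lowp = linalg.cho_factor(Vp, lower=True, check_finite=False)
        A = np.hstack([X, Zs])
        Aw = linalg.cho_solve((cp, lowp), A, check_finite=False)
        AtVA = A.T @ Aw
        D = np.zeros(A.shape[1])
        if r_s > 0:
            D[X.shape[1]:] = 1.0 / r_s
            F = linalg.solve(AtVA + np.diag(D), AtVA, assume_a="pos")
            edf_total = float(np.trace(F))
        else:
            edf_total = float(X.shape[1])
        edf_smooth = max(edf_total - 1.0, 0.0)   # subtract the intercept

    sigma = float(np.sqrt(sigma2))
    n_params = X.shape[1] + k_var
    return GaussianLMMFit(
        beta=beta, cov_beta=cov_beta, sigma_resid=sigma,
        sd_patient=sigma * np.sqrt(r_p),
        sd_spline=(sigma * np.sqrt(r_s)) if Zs is not None else None,
        loglik=loglik, aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params, edf_smooth=edf_smooth,
        n_obs=n, n_groups=m, converged=bool(res.success))
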