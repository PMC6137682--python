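"""Marginal ML fit of the log-normal response-time measurement model.

The model is a one-factor structure with equal loadings on the log scale:
``ln t_pi = xi_i - tau_p + eps_pi`` with ``tau ~ N(0, var_tau)`` and
``eps_pi ~ N(0, sigma_i^2)``.  The implied covariance of a log-time row is
compound symmetric, ``diag(sigma^2) + var_tau * 1 1'``, which permits a
closed-form profile over xi (column means) and cheap likelihood
evaluations through the matrix-determinant and Woodbury identities.
Predicted speeds are regression-method factor scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = ["RTFit", "fit_lognormal_rt", "standardized_residuals"]


@dataclass
class RTFit:
    """Estimates of the log-normal RT model."""

    xi_hat: np.ndarray
    sigma_hat: np.ndarray
    var_tau_hat: float
    tau_hat: np.ndarray
    loglik: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "xi_hat": self.xi_hat.tolist(),
            "sigma_hat": self.sigma_hat.tolist(),
            "var_tau_hat": self.var_tau_hat,
            "tau_hat": self.tau_hat.tolist(),
            "loglik": self.loglik,
        }))


def _neg_loglik(params: np.ndarray, C: np.ndarray, n: int) -> float:
    """-log L profiled over xi, as a function of (var_tau, sigma_1^2..K^2).

    C is the K x K cross-product matrix of centered log times; only O(K^2)
    work per evaluation.
    """
    v = params[0]
    s2 = params[1:]
    a = 1.0 / s2  # D^{-1} diagonal
    s = a.sum()
    denom = 1.0 + v * s
    logdet = np.log(s2).sum() + math.log(denom)
    # sum_p r' Sigma^{-1} r = tr(D^{-1} C) - v/(1+vs) * a' C a
    quad = (np.diag(C) * a).sum() - v / denom * (a @ C @ a)
    k = len(s2)
    return 0.5 * (n * logdet + quad + n * k * math.log(2 * math.pi))


def fit_lognormal_rt(T: np.ndarray) -> RTFit:
    """Marginal ML estimates of (xi, sigma, var_tau) plus factor scores."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2:
        raise ValueError("T must be an N x K matrix")
    n, k = T.shape
    if k < 3:
        raise ValueError(f"need at least 3 items to identify the factor model, got {k}")
    if n < 10:
        raise ValueError(f"need at least 10 persons, got {n}")
    if np.any(T <= 0):
        raise ValueError("all response times must be positive")
    log_t = np.log(T)
    col_var = log_t.var(axis=0)
    dead = np.flatnonzero(col_var < 1e-12)
    if dead.size:
        raise ValueError(f"item {dead[0]} has zero log-time variance")

    xi_hat = log_t.mean(axis=0)  # exact ML profile for the mean
    R = log_t - xi_hat[None, :]
    C = R.T @ R

    # moment start: common off-diagonal covariance estimates var_tau
    S = C / n
    off = S[~np.eye(k, dtype=bool)]
    v0 = max(float(off.mean()), 1e-6)
    s2_0 = np.maximum(np.diag(S) - v0, 1e-4)

    x0 = np.concatenate([[v0], s2_0])
    bounds = [(0.0, None)] + [(1e-8, None)] * k
    res = minimize(_neg_loglik, x0, args=(C, n), method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 500, "ftol": 1e-12})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("RT model optimization produced non-finite estimates")
    v = float(res.x[0])
    s2 = res.x[1:]

    # regression factor scores; loading of tau on ln t is -1
    a = 1.0 / s2
    denom = 1.0 + v * a.sum()
    tau_hat = -v * (R @ a) / denom
    return RTFit(xi_hat=xi_hat, sigma_hat=np.sqrt(s2), var_tau_hat=v,
                 tau_hat=tau_hat, loglik=-float(res.fun))


def standardized_residuals(T: np.ndarray, fit: RTFit) -> np.ndarray:
    """z_hat_pi = (ln t_pi - xi_hat_i + tau_hat_p) / sigma_hat_i."""
    T = np.asarray(T, dtype=float)
    if T.shape != (len(fit.tau_hat), len(fit.xi_hat)):
        raise ValueError("T shape does not match the fit")
    return (np.log(T) - fit.xi_hat[None, :] + fit.tau_hat[:, None]) \
        / fit.sigma_hat[None, :]


def marginal_loglik(T: np.ndarray, xi: np.ndarray, sigma: np.ndarray,
                    var_tau: float) -> float:
    """Marginal log-likelihood at arbitrary parameter values (oracle aid)."""
    T = np.asarray(T, dtype=float)
    log_t = np.log(T)
    R = log_t - np.asarray(xi, dtype=float)[None, :]
    C = R.T @ R
    params = np.concatenate([[var_tau], np.asarray(sigma, dtype=float) ** 2])
    return -_neg_loglik(params, C, T.shape[0])
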