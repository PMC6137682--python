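"""Nonparametric moderation of ICC parameters by residual log response time.

The slope and intercept of each item's probit ICC are estimated at fixed
focal points of the standardized residual log response time by maximizing
a kernel-weighted marginal likelihood in which the target item's responses
are raised to Gaussian-kernel weights and the remaining items enter with
response-specific parameters interpolated from the current curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from . import _kernels
from .models import PHI_CLIP

__all__ = [
    "FocalGrid",
    "CurveEstimates",
    "ResponseSpecificParams",
    "kernel_weights",
    "weighted_item_loglik",
    "interpolate_params",
    "estimate_curves",
    "fit_2pno_mml",
]


@dataclass(frozen=True)
class FocalGrid:
    """Focal points, bandwidth factor and the N entering the bandwidth."""

    points: tuple
    h: float = 1.1
    n: int = 0  # sample size used in the bandwidth; 0 -> take len(data)

    def __post_init__(self):
        pts = tuple(float(f) for f in self.points)
        if len(pts) < 2 or np.any(np.diff(pts) <= 0):
            raise ValueError("focal points must be >= 2 strictly ascending values")
        if self.h <= 0:
            raise ValueError("bandwidth factor h must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def j(self) -> int:
        return len(self.points)

    def bandwidth(self, n: int | None = None) -> float:
        n_eff = self.n if self.n else n
        if not n_eff or n_eff < 2:
            raise ValueError("a sample size >= 2 is required for the bandwidth")
        return self.h * n_eff ** (-0.2)


@dataclass
class CurveEstimates:
    """ICC slope/intercept at each focal point, per item."""

    alpha_curve: np.ndarray  # (K, J)
    beta_curve: np.ndarray   # (K, J)
    grid: FocalGrid
    converged: bool
    n_sweeps: int
    sum_weights: np.ndarray       # (K, J)
    low_information: np.ndarray   # (K, J) bool

    def to_frame(self) -> pd.DataFrame:
        k, j = self.alpha_curve.shape
        rows = []
        for i in range(k):
            for jj in range(j):
                rows.append((i, self.grid.points[jj], self.alpha_curve[i, jj],
                             self.beta_curve[i, jj], self.sum_weights[i, jj],
                             bool(self.low_information[i, jj])))
        return pd.DataFrame(rows, columns=["item", "focal_point", "alpha",
                                           "beta", "sum_weights", "low_information"])


@dataclass
class ResponseSpecificParams:
    """N x K response-level slopes and intercepts."""

    alpha_star: np.ndarray
    beta_star: np.ndarray


def kernel_weights(z_col: np.ndarray, focal: float, h: float, n: int) -> np.ndarray:
    """Gaussian kernel weights exp(-(z - F)^2 / (2 (h n^{-1/5})^2))."""
    if h <= 0:
        raise ValueError("h must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    bw = h * n ** (-0.2)
    d = (np.asarray(z_col, dtype=float) - focal) / bw
    return np.exp(-0.5 * d * d)


def _gh_rule(n_quad: int):
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    return nodes, np.log(weights) - 0.5 * math.log(2.0 * math.pi)


def _log_psi_cols(alpha, beta, nodes, x_col):
    """(N, Q) log Psi(alpha theta_q + beta, x_p) for per-person parameters."""
    u = np.clip(np.multiply.outer(np.asarray(alpha), nodes)
                + np.asarray(beta)[..., None], -PHI_CLIP, PHI_CLIP)
    return np.where(np.asarray(x_col)[:, None] == 1, log_ndtr(u), log_ndtr(-u))


def weighted_item_loglik(alpha_ji: float, beta_ji: float, X: np.ndarray,
                         item: int, rsp: ResponseSpecificParams,
                         w: np.ndarray, n_quad: int = 61) -> float:
    """Exact kernel-weighted marginal log-likelihood for one focal point.

    Sum over persons of the log of the Gauss-Hermite integral of
    Psi(target)^w times the product of the other items' Psi terms at their
    response-specific parameters, against a standard-normal ability.
    """
    X = np.asarray(X)
    n, k = X.shape
    nodes, log_gw = _gh_rule(n_quad)
    ll = np.zeros((n, len(nodes)))
    for kk in range(k):
        if kk == item:
            continue
        ll += _log_psi_cols(rsp.alpha_star[:, kk], rsp.beta_star[:, kk],
                            nodes, X[:, kk])
    ll += np.asarray(w, dtype=float)[:, None] * _log_psi_cols(
        np.full(n, alpha_ji), np.full(n, beta_ji), nodes, X[:, item])
    ll += log_gw[None, :]
    m = ll.max(axis=1, keepdims=True)
    out = (m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))).sum()
    if not np.isfinite(out):
        raise FloatingPointError("non-finite weighted log-likelihood")
    return float(out)


def interpolate_params(z_col: np.ndarray, alpha_row: np.ndarray,
                       beta_row: np.ndarray, grid: FocalGrid):
    """Piecewise-linear interpolation of curve values at each z.

    Values outside the focal range take the nearest endpoint.
    """
    pts = np.asarray(grid.points)
    z = np.asarray(z_col, dtype=float)
    return np.interp(z, pts, alpha_row), np.interp(z, pts, beta_row)


def fit_2pno_mml(X: np.ndarray, n_quad: int = 21, max_iter: int = 200,
                 tol: float = 1e-5):
    """Marginal-ML two-parameter normal-ogive fit (Bock-Aitkin EM).

    The ability distribution is fixed at N(0, 1).  Returns (alpha, beta)
    arrays of length K.  Used to initialize the nonparametric curves.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    nodes, log_gw = _gh_rule(n_quad)
    q = len(nodes)
    pbar = np.clip(X.mean(axis=0), 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    alpha = np.ones(k)
    beta = ndtri(pbar)
    for _ in range(max_iter):
        u = np.clip(alpha[:, None] * nodes[None, :] + beta[:, None],
                    -PHI_CLIP, PHI_CLIP)  # (K, Q)
        lp1 = log_ndtr(u)
        lp0 = log_ndtr(-u)
        # person-node posterior
        ll = X @ lp1 + (1 - X) @ lp0 + log_gw[None, :]
        m = ll.max(axis=1, keepdims=True)
        post = np.exp(ll - m)
        post /= post.sum(axis=1, keepdims=True)
        r1 = X.T @ post          # (K, Q) expected correct counts
        r0 = (1 - X).T @ post    # expected incorrect counts
        # M-step: a few Newton steps on the weighted probit likelihood
        a_new, b_new = alpha.copy(), beta.copy()
        for _ in range(5):
            u = np.clip(a_new[:, None] * nodes[None, :] + b_new[:, None],
                        -PHI_CLIP, PHI_CLIP)
            pdf = np.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
            cdf = np.clip(ndtr(u), 1e-12, 1 - 1e-12)
            w_sc = r1 * pdf / cdf - r0 * pdf / (1 - cdf)
            info = (r1 + r0) * pdf * pdf / (cdf * (1 - cdf))
            g_a = (w_sc * nodes[None, :]).sum(axis=1)
            g_b = w_sc.sum(axis=1)
            h_aa = (info * nodes[None, :] ** 2).sum(axis=1)
            h_ab = (info * nodes[None, :]).sum(axis=1)
            h_bb = info.sum(axis=1)
            det = np.maximum(h_aa * h_bb - h_ab ** 2, 1e-12)
            da = (h_bb * g_a - h_ab * g_b) / det
            db = (h_aa * g_b - h_ab * g_a) / det
            a_new = np.clip(a_new + np.clip(da, -0.5, 0.5), 0.01, 5.0)
            b_new = np.clip(b_new + np.clip(db, -0.5, 0.5), -6.0, 6.0)
        change = max(np.abs(a_new - alpha).max(), np.abs(b_new - beta).max())
        alpha, beta = a_new, b_new
        if change < tol:
            break
    return alpha, beta


def _rest_exp_matrix(total_ll: np.ndarray, item_ll: np.ndarray,
                     log_gw: np.ndarray) -> np.ndarray:
    """exp(log GH weight + rest-of-test log-lik), row-shifted for stability."""
    base = total_ll - item_ll + log_gw[None, :]
    base -= base.max(axis=1, keepdims=True)
    return np.exp(base)


def estimate_curves(X: np.ndarray, Z_hat: np.ndarray, grid: FocalGrid,
                    init: tuple | None = None, tol: float = 1e-3,
                    max_sweeps: int = 20, n_quad: int = 61,
                    weight_floor: float = 25.0, w_tol: float = 1e-9,
                    sweeps: int | None = None, update_rsp: bool = True,
                    opt_xtol: float = 1e-3):
    """Iteratively estimate ICC parameter curves over the focal grid.

    Sweeps run over items in index order and focal points left to right;
    after each item's curve is re-estimated its response-specific
    parameters are refreshed by piecewise-linear interpolation.  Stops when
    the largest absolute change across curve entries drops below ``tol``
    or after ``max_sweeps`` sweeps (``sweeps`` forces an exact number).
    With ``update_rsp=False`` the response-specific parameters stay at
    their initial values, giving a pure conditional pass (used by the
    permutation test, where it keeps the statistic exchangeable and fast).

    Returns (CurveEstimates, ResponseSpecificParams).
    """
    X = np.asarray(X)
    Z_hat = np.asarray(Z_hat, dtype=float)
    n, k = X.shape
    if Z_hat.shape != (n, k):
        raise ValueError("X and Z_hat shapes differ")
    if init is None:
        init = fit_2pno_mml(X)
    alpha0, beta0 = (np.asarray(v, dtype=float) for v in init)
    pts = np.asarray(grid.points)
    j = grid.j
    bw_n = grid.n if grid.n else n

    nodes, log_gw = _gh_rule(n_quad)
    alpha_curve = np.tile(alpha0[:, None], (1, j))
    beta_curve = np.tile(beta0[:, None], (1, j))
    alpha_star = np.tile(alpha0[None, :], (n, 1))
    beta_star = np.tile(beta0[None, :], (n, 1))

    # per-item log Psi contributions at the response-specific parameters
    item_ll = np.empty((k, n, len(nodes)))
    for i in range(k):
        item_ll[i] = _log_psi_cols(alpha_star[:, i], beta_star[:, i], nodes, X[:, i])
    total_ll = item_ll.sum(axis=0)

    sum_w = np.empty((k, j))
    x_cols = [np.ascontiguousarray(X[:, i], dtype=np.int8) for i in range(k)]
    n_sweeps_run = 0
    converged = False
    target_sweeps = sweeps if sweeps is not None else max_sweeps
    for sweep in range(target_sweeps):
        max_change = 0.0
        for i in range(k):
            E_full = _rest_exp_matrix(total_ll, item_ll[i], log_gw)
            for jj in range(j):
                w = kernel_weights(Z_hat[:, i], pts[jj], grid.h, bw_n)
                sum_w[i, jj] = w.sum()
                active = np.flatnonzero(w > w_tol)
                a_hat, b_hat, _ = _kernels.maximize_weighted_loglik(
                    alpha_curve[i, jj], beta_curve[i, jj], nodes,
                    np.ascontiguousarray(E_full[active]), w[active],
                    x_cols[i][active], xtol=opt_xtol)
                max_change = max(max_change, abs(a_hat - alpha_curve[i, jj]),
                                 abs(b_hat - beta_curve[i, jj]))
                alpha_curve[i, jj] = a_hat
                beta_curve[i, jj] = b_hat
            if not (np.isfinite(alpha_curve[i]).all()
                    and np.isfinite(beta_curve[i]).all()):
                raise FloatingPointError(
                    f"curve optimization failed for item {i}")
            if update_rsp:
                alpha_star[:, i], beta_star[:, i] = interpolate_params(
                    Z_hat[:, i], alpha_curve[i], beta_curve[i], grid)
                new_ll = _log_psi_cols(alpha_star[:, i], beta_star[:, i],
                                       nodes, X[:, i])
                total_ll += new_ll - item_ll[i]
                item_ll[i] = new_ll
        n_sweeps_run = sweep + 1
        if sweeps is None and max_change < tol:
            converged = True
            break
    if sweeps is not None:
        converged = True

    est = CurveEstimates(alpha_curve=alpha_curve, beta_curve=beta_curve,
                         grid=grid, converged=converged, n_sweeps=n_sweeps_run,
                         sum_weights=sum_w,
                         low_information=sum_w < weight_floor)
    return est, ResponseSpecificParams(alpha_star=alpha_star, beta_star=beta_star)
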