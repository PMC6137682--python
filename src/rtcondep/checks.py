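"""Permutation test of conditional independence and posterior-predictive
linearity check, both built on the nonparametric curve estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .gibbs import Chains
from .models import ModelSpec
from .npmod import FocalGrid, estimate_curves, fit_2pno_mml
from .rng import spawn_rng
from .rt_model import fit_lognormal_rt, standardized_residuals
from .simulate import (ItemSample, sample_persons, simulate_accuracy,
                       simulate_times, true_residuals)

__all__ = [
    "variance_statistic",
    "linearity_statistic",
    "PermutationResult",
    "PPCResult",
    "permutation_test",
    "ppc_linearity",
    "plot_ppc_curves",
]

PARAMS = ("alpha", "beta")


def variance_statistic(curve_row: np.ndarray) -> float:
    """Sample variance (denominator J-1) of one curve across focal points."""
    curve_row = np.asarray(curve_row, dtype=float)
    if curve_row.size < 2:
        raise ValueError("need at least two focal points")
    return float(curve_row.var(ddof=1))


def linearity_statistic(curve_row: np.ndarray, focal_points: np.ndarray) -> float:
    """Deviation from linearity: max |cumulative sum of OLS residuals|.

    The curve values are regressed on the focal points; the statistic is
    the largest absolute partial sum of the residuals, left to right.
    """
    y = np.asarray(curve_row, dtype=float)
    f = np.asarray(focal_points, dtype=float)
    if y.size != f.size or y.size < 3:
        raise ValueError("need >= 3 focal points with matching curve values")
    coef = np.polyfit(f, y, 1)
    resid = y - np.polyval(coef, f)
    return float(np.abs(np.cumsum(resid)).max())


@dataclass
class PermutationResult:
    """Observed variance statistics, permutation nulls and p-values.

    Arrays are (K, 2) with the last axis over (alpha, beta); the null
    array is (n_perm, K, 2).
    """

    observed: np.ndarray
    null: np.ndarray
    p_values: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        k = self.observed.shape[0]
        rows = []
        for i in range(k):
            for pj, name in enumerate(PARAMS):
                rows.append((i, name, self.observed[i, pj], self.p_values[i, pj],
                             self.null.shape[0]))
        return pd.DataFrame(rows, columns=["item", "parameter", "statistic",
                                           "p_value", "n_null"])


@dataclass
class PPCResult:
    """Observed linearity statistics, replicated ones and ppp values."""

    observed: np.ndarray        # (K, 2)
    replicated: np.ndarray      # (n_rep, K, 2)
    ppp: np.ndarray             # (K, 2)
    flagged: np.ndarray         # (K, 2) bool, ppp < 0.05
    observed_curves: object
    replicated_curves: np.ndarray | None = None  # (n_rep, 2, K, J) optional

    def to_frame(self) -> pd.DataFrame:
        k = self.observed.shape[0]
        rows = []
        for i in range(k):
            for pj, name in enumerate(PARAMS):
                rows.append((i, name, self.observed[i, pj], self.ppp[i, pj],
                             bool(self.flagged[i, pj])))
        return pd.DataFrame(rows, columns=["item", "parameter", "statistic",
                                           "ppp", "flagged"])


def _curve_stats(est, stat, pts):
    k = est.alpha_curve.shape[0]
    out = np.empty((k, 2))
    for i in range(k):
        if stat == "variance":
            out[i, 0] = variance_statistic(est.alpha_curve[i])
            out[i, 1] = variance_statistic(est.beta_curve[i])
        else:
            out[i, 0] = linearity_statistic(est.alpha_curve[i], pts)
            out[i, 1] = linearity_statistic(est.beta_curve[i], pts)
    return out


def permutation_test(X: np.ndarray, Z_hat: np.ndarray, grid: FocalGrid,
                     n_perm: int, seed: int, sweeps: int = 1,
                     update_rsp: bool = False, n_quad: int = 61,
                     w_tol: float = 1e-9, opt_xtol: float = 1e-3,
                     init: tuple | None = None) -> PermutationResult:
    """Permutation test of conditional independence per item and parameter.

    Each permutation independently shuffles every item's residual column
    across persons while the accuracy matrix stays intact; the curves are
    re-estimated and their variance across focal points recorded.  The
    observed and permuted statistics use the identical procedure —
    ``sweeps`` estimation sweeps from the same conditional-independence
    starting values — which makes them exchangeable under the null.  With
    the default single conditional pass (``update_rsp=False``) the
    rest-of-test matrices and the multiset of kernel weights do not depend
    on the permutation, so the null loop reduces to warm-started
    re-optimizations.  p-values carry the finite-sample +1 correction:
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X)
    Z_hat = np.asarray(Z_hat, dtype=float)
    n, k = X.shape
    if init is None:
        init = fit_2pno_mml(X)
    pts = np.asarray(grid.points)
    est_kw = dict(init=init, sweeps=sweeps, n_quad=n_quad, w_tol=w_tol,
                  update_rsp=update_rsp, opt_xtol=opt_xtol)

    est, _ = estimate_curves(X, Z_hat, grid, **est_kw)
    observed = _curve_stats(est, "variance", pts)

    rng = spawn_rng(seed, "permute")
    null = np.empty((n_perm, k, 2))
    if sweeps == 1 and not update_rsp:
        null = _permute_conditional(X, Z_hat, grid, n_perm, rng, init,
                                    n_quad, w_tol, opt_xtol)
    else:
        for b in range(n_perm):
            Zp = np.empty_like(Z_hat)
            for i in range(k):
                Zp[:, i] = Z_hat[rng.permutation(n), i]
            est_b, _ = estimate_curves(X, Zp, grid, **est_kw)
            null[b] = _curve_stats(est_b, "variance", pts)

    p = (1.0 + (null >= observed[None]).sum(axis=0)) / (n_perm + 1.0)
    return PermutationResult(observed=observed, null=null, p_values=p,
                             seed=int(seed))


def _permute_conditional(X, Z_hat, grid, n_perm, rng, init, n_quad, w_tol,
                         opt_xtol):
    """Null statistics for the single conditional pass, reusing the
    permutation-invariant rest matrices and kernel weights."""
    from . import _kernels
    from .npmod import _gh_rule, _log_psi_cols, _rest_exp_matrix, kernel_weights

    n, k = X.shape
    alpha0, beta0 = (np.asarray(v, dtype=float) for v in init)
    pts = np.asarray(grid.points)
    j = grid.j
    nodes, log_gw = _gh_rule(n_quad)
    alpha_star = np.tile(alpha0[None, :], (n, 1))
    beta_star = np.tile(beta0[None, :], (n, 1))
    item_ll = np.stack([_log_psi_cols(alpha_star[:, i], beta_star[:, i],
                                      nodes, X[:, i]) for i in range(k)])
    total_ll = item_ll.sum(axis=0)
    E = [np.ascontiguousarray(_rest_exp_matrix(total_ll, item_ll[i], log_gw))
         for i in range(k)]
    W = [[kernel_weights(Z_hat[:, i], pts[jj], grid.h, n) for jj in range(j)]
         for i in range(k)]
    x_cols = [np.ascontiguousarray(X[:, i], dtype=np.int8) for i in range(k)]

    null = np.empty((n_perm, k, 2))
    curve = np.empty((2, j))
    for b in range(n_perm):
        for i in range(k):
            perm = rng.permutation(n)
            for jj in range(j):
                w = W[i][jj][perm]
                active = np.flatnonzero(w > w_tol)
                a_hat, b_hat, _ = _kernels.maximize_weighted_loglik(
                    alpha0[i], beta0[i], nodes,
                    np.ascontiguousarray(E[i][active]), w[active],
                    x_cols[i][active], xtol=opt_xtol)
                curve[0, jj] = a_hat
                curve[1, jj] = b_hat
            null[b, i, 0] = variance_statistic(curve[0])
            null[b, i, 1] = variance_statistic(curve[1])
    return null


def ppc_linearity(chains: Chains, data: Dataset, grid: FocalGrid,
                  n_rep: int, seed: int, thinning: int | None = None,
                  estimator_kwargs: dict | None = None,
                  observed_curves=None, keep_curves: bool = False) -> PPCResult:
    """Posterior-predictive check of linear conditional dependence.

    For each retained draw used, a full replicate dataset (times and
    accuracies) is simulated under the linear conditional dependence model
    and pushed through the complete two-step nonparametric pipeline
    (response-time fit, residuals, curve estimation).  The discrepancy is
    the max-|cumsum| linearity statistic; ppp is the proportion of
    replicates with a statistic at least as large as the observed one.
    Items with ppp < 0.05 are flagged.
    """
    if chains.model.kind != "linear":
        raise ValueError("posterior-predictive linearity check requires chains "
                         f"from the linear model, got {chains.model.kind!r}")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    kw = dict(estimator_kwargs or {})
    pts = np.asarray(grid.points)
    n = data.n_persons

    if observed_curves is None:
        fit = fit_lognormal_rt(data.T)
        z_obs = standardized_residuals(data.T, fit)
        observed_curves, _ = estimate_curves(data.X, z_obs, grid, **kw)
    observed = _curve_stats(observed_curves, "linearity", pts)

    n_draws = chains.n_draws
    if thinning is not None:
        idx = np.arange(0, n_draws, int(thinning))[:n_rep]
        if len(idx) < n_rep:
            raise ValueError("not enough retained draws for the requested "
                             "n_rep at this thinning")
    else:
        idx = np.unique(np.linspace(0, n_draws - 1, n_rep).round().astype(int))
    rng_root = spawn_rng(seed, "ppc")
    model = ModelSpec(kind="linear")

    replicated = np.empty((len(idx), data.n_items, 2))
    curves = [] if keep_curves else None
    for r, t in enumerate(idx):
        A_t = chains.draws["A"][t]
        items = ItemSample(A=A_t, xi=chains.draws["xi"][t],
                           sigma=chains.draws["sigma"][t])
        b = chains.draws["b"][t]
        vt = chains.draws["var_tau"][t]
        Sigma_P = np.array([[1.0, b], [b, max(vt, b * b + 1e-8)]])
        streams = rng_root.spawn(3)
        persons = sample_persons(n, Sigma_P, streams[0])
        T_rep = simulate_times(persons, items.xi, items.sigma, streams[1])
        Z_true = true_residuals(T_rep, persons, items.xi, items.sigma)
        X_rep = simulate_accuracy(model, persons, items, Z_true, streams[2])
        fit_rep = fit_lognormal_rt(T_rep)
        z_rep = standardized_residuals(T_rep, fit_rep)
        est_rep, _ = estimate_curves(X_rep, z_rep, grid, **kw)
        replicated[r] = _curve_stats(est_rep, "linearity", pts)
        if keep_curves:
            curves.append(np.stack([est_rep.alpha_curve, est_rep.beta_curve]))

    ppp = (replicated >= observed[None]).mean(axis=0)
    return PPCResult(observed=observed, replicated=replicated, ppp=ppp,
                     flagged=ppp < 0.05, observed_curves=observed_curves,
                     replicated_curves=np.stack(curves) if keep_curves else None)


def plot_ppc_curves(result: PPCResult, item: int, parameter: str = "beta",
                    path=None):
    """Spaghetti plot of replicated curves (gray) vs the observed curve
    (black) for one item; requires ``ppc_linearity(..., keep_curves=True)``.
    """
    if result.replicated_curves is None:
        raise ValueError("run ppc_linearity with keep_curves=True first")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pj = PARAMS.index(parameter)
    pts = np.asarray(result.observed_curves.grid.points)
    obs = (result.observed_curves.alpha_curve if pj == 0
           else result.observed_curves.beta_curve)[item]
    fig, ax = plt.subplots(figsize=(5, 4))
    for rep in result.replicated_curves[:, pj, item]:
        ax.plot(pts, rep, color="0.7", lw=0.8)
    ax.plot(pts, obs, color="black", lw=2)
    ax.set_xlabel("residual log response time")
    ax.set_ylabel(f"ICC {parameter}, item {item}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
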