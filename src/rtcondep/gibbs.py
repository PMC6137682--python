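"""Metropolis-within-Gibbs estimation of the joint models.

Sampler layout (one iteration):

1. person pairs (theta_p, tau_p): joint random-walk Metropolis with the
   latent continuous responses integrated out; the residual z_pi is
   recomputed from the proposed tau so the accuracy side sees the move
2. item time parameters (xi_i, sigma_i): independence Metropolis-Hastings
   proposing from the (mildly overdispersed) time-side conditional,
   followed by a small symmetric random-walk refinement in (xi, ln sigma);
   z is recomputed under every proposal
3. latent continuous responses x*: exact truncated-normal draws
4. item accuracy coefficient vectors: conjugate normal regression updates
   given x*, with the prior conditioned on the item's current xi
5. person covariance: tau-on-theta regression (b, omega^2) with a
   normal/inverse-gamma update; Sigma_P = [[1, b], [b, b^2 + omega^2]]
   keeps the theta variance at one by construction
6. item hyper-parameters (mu_I, Sigma_I): semi-conjugate normal and
   inverse-Wishart updates

Proposal scales adapt toward a 20-50% acceptance rate during burn-in and
are frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .data import AnalysisConfig, Dataset
from .models import PHI_CLIP, ItemParams, ModelSpec, log_psi
from .rng import spawn_rng

__all__ = ["Chains", "run_gibbs", "model_spec_from_config"]


def model_spec_from_config(config: AnalysisConfig) -> ModelSpec:
    return ModelSpec(kind=config.model, thresholds=config.multicat_thresholds,
                     baseline=config.multicat_baseline)


@dataclass
class Chains:
    """Post-burn-in, thinned posterior draws with bookkeeping."""

    model: ModelSpec
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    draws: dict  # name -> array with leading draw axis
    accept_person: float
    accept_item: float
    theta_mean: np.ndarray
    tau_mean: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.draws["xi"].shape[0]

    def posterior_means(self):
        """(items, Sigma_P) at posterior means of the item parameters."""
        A = self.draws["A"].mean(axis=0)
        xi = self.draws["xi"].mean(axis=0)
        sigma = self.draws["sigma"].mean(axis=0)
        items = [ItemParams.from_acc_vector(self.model, A[i], xi=xi[i], sigma=sigma[i])
                 for i in range(A.shape[0])]
        b = self.draws["b"].mean()
        vt = self.draws["var_tau"].mean()
        Sigma_P = np.array([[1.0, b], [b, vt]])
        return items, Sigma_P

    def parameter_table(self) -> pd.DataFrame:
        """One row per scalar parameter: mean, sd, 2.5% and 97.5% quantiles."""
        rows = []
        names = self.model.acc_param_names
        for name, arr in self.draws.items():
            if arr.ndim == 1:
                rows.append((name, arr))
            elif arr.ndim == 2:
                for i in range(arr.shape[1]):
                    rows.append((f"{name}[{i}]", arr[:, i]))
            else:
                for i in range(arr.shape[1]):
                    for j in range(arr.shape[2]):
                        rows.append((f"{names[j]}[{i}]", arr[:, i, j]))
        out = pd.DataFrame({
            "parameter": [r[0] for r in rows],
            "mean": [r[1].mean() for r in rows],
            "sd": [r[1].std(ddof=1) for r in rows],
            "q2.5": [np.quantile(r[1], 0.025) for r in rows],
            "q97.5": [np.quantile(r[1], 0.975) for r in rows],
        })
        return out

    def credible_interval(self, name: str, level: float = 0.95) -> np.ndarray:
        """Equal-tailed intervals for a draw array; shape (..., 2)."""
        arr = self.draws[name]
        lo = (1 - level) / 2
        return np.stack([np.quantile(arr, lo, axis=0),
                         np.quantile(arr, 1 - lo, axis=0)], axis=-1)


def _truncnorm_draws(mean: np.ndarray, x: np.ndarray, rng) -> np.ndarray:
    """x* ~ N(mean, 1) truncated to x*>0 where x=1 and x*<0 where x=0."""
    u = rng.random(mean.shape)
    pos = x == 1
    out = np.empty_like(mean)
    # stable tail forms via the complementary cdf
    p_up = (1.0 - u[pos]) * ndtr(mean[pos])
    out[pos] = mean[pos] - ndtri(np.maximum(p_up, 1e-300))
    p_lo = u[~pos] * ndtr(-mean[~pos])
    out[~pos] = mean[~pos] + ndtri(np.maximum(p_lo, 1e-300))
    return out


def _acc_loglik_rows(model, A, z, theta, X):
    """Per-(p,i) accuracy log-likelihood matrix."""
    s, c = model.slope_intercept(A, z)
    return log_psi(s * theta[:, None] + c, X)


def run_gibbs(data: Dataset, config: AnalysisConfig, seed: int | None = None,
              iteration_hook=None) -> Chains:
    """Sample the posterior of the configured joint model.

    ``iteration_hook(i, state)``, if given, is called with the mutable
    sampler state after every iteration (probing/diagnostics only).
    """
    model = model_spec_from_config(config)
    seed = config.seed if seed is None else int(seed)
    rng = spawn_rng(seed, "gibbs", model.kind)

    X = np.asarray(data.X, dtype=np.int8)
    log_t = np.log(np.asarray(data.T, dtype=float))
    n, k = X.shape
    d_acc = model.n_acc_params
    d = d_acc + 1  # accuracy coefficients + xi in the hyper vector

    # ---- initial state ------------------------------------------------
    xi = log_t.mean(axis=0)
    tau = -(log_t - xi[None, :]).mean(axis=1)
    tau -= tau.mean()
    resid = log_t - xi[None, :] + tau[:, None]
    sigma = np.maximum(resid.std(axis=0), 1e-3)
    score = X.mean(axis=1)
    theta = (score - score.mean()) / max(score.std(), 1e-6)
    pbar = np.clip(X.mean(axis=0), 0.02, 0.98)
    A = np.zeros((k, d_acc))
    if model.kind == "multicat":
        A[:, 0] = 1.0
        A[:, model.n_categories] = ndtri(pbar)
    else:
        A[:, 0] = 1.0
        A[:, d_acc // 2] = ndtri(pbar)
    b = 0.0
    omega2 = max(float(tau.var()), 1e-3)
    V = np.column_stack([A, xi])
    mu_I = V.mean(axis=0)
    Sigma_I = np.eye(d) * 0.5

    # priors
    mu_prior_prec = 1e-4          # mu_I ~ N(0, 100^2 I)
    iw_df0, iw_scale0 = d + 2, np.eye(d)
    kappa_b, ig_a0, ig_b0 = 0.01, 2.0, 0.5   # (b, omega^2) prior
    lnsig_sd0 = 10.0              # ln sigma ~ N(0, 10^2)

    # adaptive RW scale for the person block
    step_p = np.full(n, 0.5)
    acc_p = np.zeros(n)
    acc_p_total = acc_i_total = 0.0
    batch = 50

    z = (log_t - xi[None, :] + tau[:, None]) / sigma[None, :]

    n_keep = (config.n_iter - config.burn_in) // config.thin
    keep = {
        "A": np.empty((n_keep, k, d_acc)),
        "xi": np.empty((n_keep, k)),
        "sigma": np.empty((n_keep, k)),
        "b": np.empty(n_keep),
        "var_tau": np.empty(n_keep),
        "mu_I": np.empty((n_keep, d)),
    }
    theta_sum = np.zeros(n)
    tau_sum = np.zeros(n)
    kept = 0

    tau_scale = 1.0

    for it in range(config.n_iter):
        # ---- 1. persons -----------------------------------------------
        acc_ll = _acc_loglik_rows(model, A, z, theta, X)
        time_ll = -0.5 * (z ** 2)
        cur = acc_ll.sum(axis=1) + time_ll.sum(axis=1) \
            - 0.5 * theta ** 2 - 0.5 * (tau - b * theta) ** 2 / omega2
        prop = rng.standard_normal((n, 2))
        theta_n = theta + step_p * prop[:, 0]
        tau_n = tau + step_p * tau_scale * prop[:, 1]
        z_n = (log_t - xi[None, :] + tau_n[:, None]) / sigma[None, :]
        acc_ll_n = _acc_loglik_rows(model, A, z_n, theta_n, X)
        new = acc_ll_n.sum(axis=1) - 0.5 * (z_n ** 2).sum(axis=1) \
            - 0.5 * theta_n ** 2 - 0.5 * (tau_n - b * theta_n) ** 2 / omega2
        accept = np.log(rng.random(n)) < new - cur
        theta = np.where(accept, theta_n, theta)
        tau = np.where(accept, tau_n, tau)
        z = np.where(accept[:, None], z_n, z)
        acc_p += accept
        acc_p_total += accept.mean()

        # ---- 2. item time parameters ----------------------------------
        # independence MH: propose (xi, sigma^2) from the time-side
        # conditional (normal / inverse-gamma built from t and tau only);
        # the acceptance ratio then carries the accuracy-side change and
        # the weak priors, and acceptance stays near one
        acc_ll = _acc_loglik_rows(model, A, z, theta, X)
        ln_sigma = np.log(sigma)
        # conditional prior of xi given the accuracy coefficients
        Saa = Sigma_I[:d_acc, :d_acc]
        Sxa = Sigma_I[d_acc, :d_acc]
        sol = np.linalg.solve(Saa, Sxa)
        cond_var = max(float(Sigma_I[d_acc, d_acc] - Sxa @ sol), 1e-10)
        cond_mean = mu_I[d_acc] + (A - mu_I[None, :d_acc]) @ sol

        resid0 = log_t + tau[:, None]              # ln t + tau, mean xi_i
        m_q = resid0.mean(axis=0)
        s2_hat = resid0.var(axis=0)
        # proposal is mildly overdispersed relative to the time-side
        # conditional so that the accuracy-side shift of the target stays
        # inside the proposal's support
        v_xi = 2.0 * s2_hat / n
        a_q = 0.25 * n
        xi_n = m_q + np.sqrt(v_xi) * rng.standard_normal(k)
        b_q_n = (a_q + 1.0) * ((resid0 - xi_n[None, :]) ** 2).mean(axis=0)
        sig2_n = b_q_n / rng.gamma(a_q, size=k)
        sigma_n = np.sqrt(sig2_n)
        lns_n = 0.5 * np.log(sig2_n)
        b_q_c = (a_q + 1.0) * ((resid0 - xi[None, :]) ** 2).mean(axis=0)
        sig2_c = sigma ** 2

        def _log_q(xi_v, sig2_v, b_q_v):
            return (-0.5 * (xi_v - m_q) ** 2 / v_xi
                    + a_q * np.log(b_q_v) - (a_q + 1.0) * np.log(sig2_v)
                    - b_q_v / sig2_v)

        def _log_target(acc, xi_v, lns_v, sig2_v, zsq, cm):
            # time likelihood + accuracy + conditional hyper prior on xi
            # + N(0, lnsig_sd0^2) prior on ln sigma (with d ln sigma ->
            # d sigma^2 Jacobian)
            return (acc - 0.5 * n * np.log(sig2_v) - 0.5 * zsq
                    - 0.5 * (xi_v - cm) ** 2 / cond_var
                    - 0.5 * lns_v ** 2 / lnsig_sd0 ** 2 - np.log(2.0 * sig2_v))

        z_n = (log_t - xi_n[None, :] + tau[:, None]) / sigma_n[None, :]
        acc_ll_n = _acc_loglik_rows(model, A, z_n, theta, X)
        logr = (_log_target(acc_ll_n.sum(axis=0), xi_n, lns_n, sig2_n,
                            (z_n ** 2).sum(axis=0), cond_mean)
                - _log_target(acc_ll.sum(axis=0), xi, ln_sigma, sig2_c,
                              (z ** 2).sum(axis=0), cond_mean)
                + _log_q(xi, sig2_c, b_q_c) - _log_q(xi_n, sig2_n, b_q_n))
        accept = np.log(rng.random(k)) < logr
        xi = np.where(accept, xi_n, xi)
        sigma = np.where(accept, sigma_n, sigma)
        z = np.where(accept[None, :], z_n, z)
        acc_i_total += accept.mean()

        # small random-walk refinement of the same block: improves local
        # mixing when the accuracy side reacts sharply to z (multicat)
        acc_ll = np.where(accept[None, :], acc_ll_n, acc_ll)
        ln_sigma = np.log(sigma)
        sig2_c = sigma ** 2
        step = np.sqrt(s2_hat / n)
        xi_r = xi + step * rng.standard_normal(k)
        lns_r = ln_sigma + (1.0 / math.sqrt(2.0 * n)) * rng.standard_normal(k)
        sigma_r = np.exp(lns_r)
        z_r = (log_t - xi_r[None, :] + tau[:, None]) / sigma_r[None, :]
        acc_ll_r = _acc_loglik_rows(model, A, z_r, theta, X)
        # symmetric proposal in (xi, ln sigma); express the target wrt the
        # same coordinates (drop the sigma^2 Jacobian on both sides)
        logr = (_log_target(acc_ll_r.sum(axis=0), xi_r, lns_r, sigma_r ** 2,
                            (z_r ** 2).sum(axis=0), cond_mean)
                + np.log(2.0 * sigma_r ** 2)
                - _log_target(acc_ll.sum(axis=0), xi, ln_sigma, sig2_c,
                              (z ** 2).sum(axis=0), cond_mean)
                - np.log(2.0 * sig2_c))
        accept = np.log(rng.random(k)) < logr
        xi = np.where(accept, xi_r, xi)
        sigma = np.where(accept, sigma_r, sigma)
        z = np.where(accept[None, :], z_r, z)

        # ---- 3. latent continuous responses ---------------------------
        s, c = model.slope_intercept(A, z)
        pred = np.clip(s * theta[:, None] + c, -PHI_CLIP, PHI_CLIP)
        x_star = _truncnorm_draws(pred, X, rng)

        # ---- 4. item accuracy coefficients ----------------------------
        Sax = Sxa  # Cov(a, xi) block
        sol_x = Sax / max(float(Sigma_I[d_acc, d_acc]), 1e-10)
        S_c = Saa - np.outer(Sax, sol_x)
        S_c_inv = np.linalg.inv(S_c + 1e-10 * np.eye(d_acc))
        for i in range(k):
            m_c = mu_I[:d_acc] + sol_x * (xi[i] - mu_I[d_acc])
            D = model.design(theta, z[:, i])
            prec = S_c_inv + D.T @ D
            cov = np.linalg.inv(prec)
            mean = cov @ (S_c_inv @ m_c + D.T @ x_star[:, i])
            L = np.linalg.cholesky((cov + cov.T) / 2)
            A[i] = mean + L @ rng.standard_normal(d_acc)

        # ---- 5. person covariance -------------------------------------
        kap_n = kappa_b + float(theta @ theta)
        b_hat = float(theta @ tau) / kap_n
        a_n = ig_a0 + n / 2.0
        b_n = ig_b0 + 0.5 * (float(tau @ tau) - b_hat ** 2 * kap_n)
        omega2 = float(b_n / rng.gamma(a_n))
        b = b_hat + math.sqrt(omega2 / kap_n) * rng.standard_normal()
        tau_scale = math.sqrt(b * b + omega2)

        # ---- 6. item hyper-parameters ---------------------------------
        V = np.column_stack([A, xi])
        Sig_inv = np.linalg.inv(Sigma_I)
        post_prec = mu_prior_prec * np.eye(d) + k * Sig_inv
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (Sig_inv @ V.sum(axis=0))
        Lm = np.linalg.cholesky((post_cov + post_cov.T) / 2)
        mu_I = post_mean + Lm @ rng.standard_normal(d)
        Rv = V - mu_I[None, :]
        Sigma_I = invwishart.rvs(df=iw_df0 + k, scale=iw_scale0 + Rv.T @ Rv,
                                 random_state=rng)
        Sigma_I = np.atleast_2d(Sigma_I)

        if not (np.isfinite(A).all() and np.isfinite(xi).all()
                and np.isfinite(sigma).all() and math.isfinite(omega2)):
            raise FloatingPointError(f"divergent chain at iteration {it}")

        # ---- adaptation (burn-in only) --------------------------------
        if it < config.burn_in and (it + 1) % batch == 0:
            rate_p = acc_p / batch
            step_p *= np.exp(0.15 * np.where(rate_p > 0.3, 1.0, -1.0))
            step_p = np.clip(step_p, 1e-3, 5.0)
            acc_p[:] = 0

        if iteration_hook is not None:
            iteration_hook(it, {"theta": theta, "tau": tau, "xi": xi,
                                "sigma": sigma, "A": A, "z": z, "b": b,
                                "omega2": omega2})

        # ---- storage --------------------------------------------------
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and kept < n_keep:
            keep["A"][kept] = A
            keep["xi"][kept] = xi
            keep["sigma"][kept] = sigma
            keep["b"][kept] = b
            keep["var_tau"][kept] = b * b + omega2
            keep["mu_I"][kept] = mu_I
            theta_sum += theta
            tau_sum += tau
            kept += 1

    return Chains(model=model, seed=seed, n_iter=config.n_iter,
                  burn_in=config.burn_in, thin=config.thin, draws=keep,
                  accept_person=acc_p_total / config.n_iter,
                  accept_item=acc_i_total / config.n_iter,
                  theta_mean=theta_sum / max(kept, 1),
                  tau_mean=tau_sum / max(kept, 1))
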