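"""Joint densities for accuracy and response time.

Four accuracy-side model kinds are supported, all probit ICCs whose slope
and intercept may depend on the standardized residual log response time z:

- ``ci``        slope/intercept constant in z (conditional independence)
- ``linear``    slope and intercept linear in z
- ``quadratic`` slope and intercept quadratic in z
- ``multicat``  slope and intercept piecewise constant over z-categories
                defined by fixed thresholds, with contrasts relative to a
                baseline category

The response-time side is always the log-normal model
``ln t ~ N(xi - tau, sigma^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "PHI_CLIP",
    "ModelSpec",
    "ItemParams",
    "icc_probability",
    "bvn_conditional_prob",
    "psi",
    "log_psi",
    "minus2_loglik",
    "modified_bic",
    "cd_param_count",
    "n_params",
]

# probit arguments are clipped here before Phi; the induced probability
# error is < 1e-15 while protecting log-likelihoods from -inf
PHI_CLIP = 8.0


def _phi(a):
    return ndtr(np.clip(a, -PHI_CLIP, PHI_CLIP))


def psi(a, x):
    """Psi(a, x) = Phi(a)^x (1 - Phi(a))^(1-x) for binary x."""
    p = _phi(a)
    x = np.asarray(x)
    return np.where(x == 1, p, 1.0 - p)


def log_psi(a, x):
    a = np.clip(a, -PHI_CLIP, PHI_CLIP)
    x = np.asarray(x)
    return np.where(x == 1, log_ndtr(a), log_ndtr(-a))


@dataclass(frozen=True)
class ModelSpec:
    """Model kind plus the fixed category structure of the multicat model."""

    kind: str
    thresholds: tuple = (-1.5, -0.5, 0.5, 1.5)
    baseline: int = 2

    def __post_init__(self):
        if self.kind not in ("ci", "linear", "quadratic", "multicat"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        thr = tuple(float(q) for q in self.thresholds)
        if np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        object.__setattr__(self, "thresholds", thr)
        if self.kind == "multicat" and not 0 <= self.baseline <= len(thr):
            raise ValueError("baseline category out of range")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def n_acc_params(self) -> int:
        """Length of the per-item accuracy coefficient vector."""
        return {"ci": 2, "linear": 4, "quadratic": 6,
                "multicat": 2 * self.n_categories}[self.kind]

    @property
    def acc_param_names(self) -> list:
        if self.kind == "ci":
            return ["alpha0", "beta0"]
        if self.kind == "linear":
            return ["alpha0", "alpha1", "beta0", "beta1"]
        if self.kind == "quadratic":
            return ["alpha0", "alpha1", "alpha2", "beta0", "beta1", "beta2"]
        m, M = self.baseline, self.n_categories
        ks = [k for k in range(M) if k != m]
        return (["alpha_base"] + [f"alpha_cat{k}" for k in ks]
                + ["beta_base"] + [f"beta_cat{k}" for k in ks])

    def categories(self, z: np.ndarray) -> np.ndarray:
        """Category index in 0..M-1 for each z (q_k <= z < q_{k+1})."""
        return np.searchsorted(np.asarray(self.thresholds), z, side="right")

    def slope_intercept(self, A: np.ndarray, z: np.ndarray):
        """Slope s and intercept c of the probit predictor s*theta + c.

        A is a (K, d) stack of item coefficient vectors; z is (N, K).
        Returns (N, K) arrays broadcast over persons.
        """
        A = np.atleast_2d(A)
        z = np.asarray(z, dtype=float)
        if self.kind == "ci":
            s = np.broadcast_to(A[:, 0], z.shape)
            c = np.broadcast_to(A[:, 1], z.shape)
        elif self.kind == "linear":
            s = A[:, 0] + A[:, 1] * z
            c = A[:, 2] + A[:, 3] * z
        elif self.kind == "quadratic":
            z2 = z * z
            s = A[:, 0] + A[:, 1] * z + A[:, 2] * z2
            c = A[:, 3] + A[:, 4] * z + A[:, 5] * z2
        else:
            M, m = self.n_categories, self.baseline
            cat = self.categories(z)  # (N, K)
            # expand contrast columns to a full per-category table with the
            # baseline contrast fixed at zero
            ks = [k for k in range(M) if k != m]
            alpha_tab = np.zeros((A.shape[0], M))
            beta_tab = np.zeros((A.shape[0], M))
            alpha_tab[:, ks] = A[:, 1:M]
            beta_tab[:, ks] = A[:, M + 1:]
            s = A[:, 0] + alpha_tab[np.arange(A.shape[0])[None, :], cat]
            c = A[:, M] + beta_tab[np.arange(A.shape[0])[None, :], cat]
        return s, c

    def design(self, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Per-response design rows d such that predictor = d @ a_i.

        theta and z are length-N vectors for one item; returns (N, d).
        """
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        one = np.ones_like(theta)
        if self.kind == "ci":
            return np.column_stack([theta, one])
        if self.kind == "linear":
            return np.column_stack([theta, z * theta, one, z])
        if self.kind == "quadratic":
            z2 = z * z
            return np.column_stack([theta, z * theta, z2 * theta, one, z, z2])
        M, m = self.n_categories, self.baseline
        cat = self.categories(z)
        cols = [theta]
        for k in range(M):
            if k != m:
                cols.append(theta * (cat == k))
        cols.append(one)
        for k in range(M):
            if k != m:
                cols.append((cat == k).astype(float))
        return np.column_stack(cols)


@dataclass
class ItemParams:
    """Coefficients of a single item.

    ``alpha0``/``beta0`` are the baseline slope/intercept (the baseline
    *category* values under the multicat model); the linear and quadratic
    effect fields are exactly zero for model kinds that lack them.
    ``alpha_cat``/``beta_cat`` hold the length-M category contrasts with a
    structural zero at the baseline category.
    """

    alpha0: float
    beta0: float
    alpha1: float = 0.0
    beta1: float = 0.0
    alpha2: float = 0.0
    beta2: float = 0.0
    alpha_cat: np.ndarray | None = None
    beta_cat: np.ndarray | None = None
    xi: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def acc_vector(self, model: ModelSpec) -> np.ndarray:
        if model.kind == "ci":
            return np.array([self.alpha0, self.beta0])
        if model.kind == "linear":
            return np.array([self.alpha0, self.alpha1, self.beta0, self.beta1])
        if model.kind == "quadratic":
            return np.array([self.alpha0, self.alpha1, self.alpha2,
                             self.beta0, self.beta1, self.beta2])
        M, m = model.n_categories, model.baseline
        a = np.zeros(M) if self.alpha_cat is None else np.asarray(self.alpha_cat, float)
        b = np.zeros(M) if self.beta_cat is None else np.asarray(self.beta_cat, float)
        ks = [k for k in range(M) if k != m]
        return np.concatenate([[self.alpha0], a[ks], [self.beta0], b[ks]])

    @staticmethod
    def from_acc_vector(model: ModelSpec, vec: np.ndarray,
                        xi: float = 0.0, sigma: float = 1.0) -> "ItemParams":
        vec = np.asarray(vec, dtype=float)
        if model.kind == "ci":
            return ItemParams(alpha0=vec[0], beta0=vec[1], xi=xi, sigma=sigma)
        if model.kind == "linear":
            return ItemParams(alpha0=vec[0], alpha1=vec[1], beta0=vec[2],
                              beta1=vec[3], xi=xi, sigma=sigma)
        if model.kind == "quadratic":
            return ItemParams(alpha0=vec[0], alpha1=vec[1], alpha2=vec[2],
                              beta0=vec[3], beta1=vec[4], beta2=vec[5],
                              xi=xi, sigma=sigma)
        M, m = model.n_categories, model.baseline
        ks = [k for k in range(M) if k != m]
        a = np.zeros(M)
        b = np.zeros(M)
        a[ks] = vec[1:M]
        b[ks] = vec[M + 1:]
        return ItemParams(alpha0=vec[0], beta0=vec[M], alpha_cat=a, beta_cat=b,
                          xi=xi, sigma=sigma)


def icc_probability(model: ModelSpec, item: ItemParams, theta, z):
    """P(correct | theta, z) under the given model kind."""
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    a = item.acc_vector(model)[None, :]
    s, c = model.slope_intercept(a, np.atleast_2d(z.reshape(-1)).T)
    pred = s[:, 0] * theta.reshape(-1) + c[:, 0]
    out = _phi(pred)
    return out.reshape(np.broadcast(theta, z).shape) if out.size > 1 else float(out[0])


def bvn_conditional_prob(theta, tau, alpha, beta, xi, sigma, rho, t):
    """P(correct | t) when (x*, ln t) are jointly bivariate normal.

    The latent response x* has mean alpha*theta + beta and unit variance,
    ln t has mean xi - tau and variance sigma^2, and rho is the conditional
    correlation between them.  Conditioning on t gives
    Phi((alpha*theta + beta + rho*z) / sqrt(1 - rho^2)) with
    z = (ln t - xi + tau) / sigma.
    """
    rho = float(rho)
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    z = (np.log(t) - xi + np.asarray(tau)) / sigma
    arg = (alpha * np.asarray(theta) + beta + rho * z) / math.sqrt(1.0 - rho * rho)
    out = ndtr(arg)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def _log_time_density(log_t: np.ndarray, xi: np.ndarray, tau, sigma: np.ndarray):
    """log of the log-normal time density, vectorized over (N, K)."""
    mu = xi[None, :] - np.asarray(tau).reshape(-1, 1)
    return (-log_t - np.log(sigma)[None, :] - 0.5 * math.log(2 * math.pi)
            - 0.5 * ((log_t - mu) / sigma[None, :]) ** 2)


def _log_time_density_3d(log_t: np.ndarray, xi: np.ndarray, tau_c, sigma: np.ndarray):
    """Same density with a leading quadrature-chunk axis; tau_c is (C, 1, 1)."""
    resid = (log_t[None, :, :] - xi[None, None, :] + tau_c) / sigma[None, None, :]
    return (-log_t[None, :, :] - np.log(sigma)[None, None, :]
            - 0.5 * math.log(2 * math.pi) - 0.5 * resid ** 2)


def minus2_loglik(data, model: ModelSpec, items, Sigma_P: np.ndarray,
                  n_quad: int = 31) -> float:
    """-2 marginal log-likelihood with (theta, tau) integrated out.

    The double integral over the bivariate-normal person distribution is
    evaluated by tensor-product Gauss-Hermite quadrature after a Cholesky
    transform of ``Sigma_P``.
    """
    from scipy.special import logsumexp

    A = np.vstack([it.acc_vector(model) for it in items])
    xi = np.array([it.xi for it in items])
    sigma = np.array([it.sigma for it in items])
    X = np.asarray(data.X)
    log_t = np.log(np.asarray(data.T, dtype=float))
    L = np.linalg.cholesky(np.asarray(Sigma_P, dtype=float))
    n, k = X.shape

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    # hermegauss weights integrate against exp(-x^2/2); dividing by
    # sqrt(2*pi) per dimension makes them standard-normal weights
    log_w = np.log(weights) - 0.5 * math.log(2 * math.pi)
    n1, n2 = np.meshgrid(nodes, nodes, indexing="ij")
    theta_all = (L[0, 0] * n1).ravel()
    tau_all = (L[1, 0] * n1 + L[1, 1] * n2).ravel()
    log_wts = (log_w[:, None] + log_w[None, :]).ravel()

    m = theta_all.size
    ll_nodes = np.empty((m, n))
    chunk = max(1, int(2e6 // (n * k)))  # bound scratch memory
    for s0 in range(0, m, chunk):
        sl = slice(s0, min(s0 + chunk, m))
        tau_c = tau_all[sl][:, None, None]
        z = (log_t[None, :, :] - xi[None, None, :] + tau_c) / sigma[None, None, :]
        s, c = model.slope_intercept(A, z)
        pred = s * theta_all[sl][:, None, None] + c
        ll = log_psi(pred, X[None, :, :]) \
            + _log_time_density_3d(log_t, xi, tau_c, sigma)
        ll_nodes[sl] = ll.sum(axis=2)
    lse = logsumexp(ll_nodes + log_wts[:, None], axis=0)
    if not np.all(np.isfinite(lse)):
        raise FloatingPointError("non-finite marginal likelihood under quadrature")
    return float(-2.0 * lse.sum())


def modified_bic(m2ll: float, n_params: int, n_persons: int) -> float:
    """BIC evaluated at posterior means: -2LL + P * ln(N persons)."""
    if n_params <= 0:
        raise ValueError("n_params must be positive")
    if n_persons <= 1:
        raise ValueError("n_persons must exceed 1")
    return float(m2ll + n_params * math.log(n_persons))


def cd_param_count(model: ModelSpec, n_items: int) -> int:
    """Number of conditional-dependence parameters beyond the CI model.

    This is the incremental count reported alongside fit statistics:
    0 for CI, 2K for linear, 4K for quadratic and 2(M-1)K for the
    multiple-category model.
    """
    extra = {"ci": 0, "linear": 2, "quadratic": 4,
             "multicat": 2 * (model.n_categories - 1)}[model.kind]
    return extra * n_items


def n_params(model: ModelSpec, n_items: int, include_hyper: bool = True) -> int:
    """Documented full parameter count for the modified BIC penalty.

    Per item: the accuracy coefficient vector, xi and sigma.  Hyper level:
    mu_I, the free entries of Sigma_I, and the two free entries of the
    person covariance (its theta variance is fixed at one).
    """
    d = model.n_acc_params + 1  # accuracy coefficients + xi
    count = n_items * (d + 1)  # + sigma per item
    if include_hyper:
        count += d + d * (d + 1) // 2 + 2
    return count
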