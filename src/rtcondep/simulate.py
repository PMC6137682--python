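"""Generative simulation of persons, items, response times and accuracies.

Data can be generated under any of the four model kinds, either from
explicitly supplied item parameters (for recovery studies) or with item
parameter vectors drawn from a multivariate-normal hyper distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import Dataset
from .models import ModelSpec, _phi
from .rng import spawn_rng

__all__ = [
    "PersonSample",
    "ItemSample",
    "GeneratingSpec",
    "sample_persons",
    "sample_items",
    "simulate_times",
    "true_residuals",
    "simulate_accuracy",
    "simulate_dataset",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return spawn_rng(int(seed), "simulate")


@dataclass
class PersonSample:
    """Latent abilities and speeds drawn from N2(0, Sigma_P)."""

    theta: np.ndarray
    tau: np.ndarray
    Sigma_P: np.ndarray

    @property
    def n(self) -> int:
        return len(self.theta)


@dataclass
class ItemSample:
    """Item parameters: accuracy coefficient stack A (K x d), xi, sigma."""

    A: np.ndarray
    xi: np.ndarray
    sigma: np.ndarray

    @property
    def k(self) -> int:
        return len(self.xi)


def _check_sigma_p(Sigma_P: np.ndarray) -> np.ndarray:
    Sigma_P = np.asarray(Sigma_P, dtype=float)
    if Sigma_P.shape != (2, 2):
        raise ValueError("Sigma_P must be 2x2")
    if abs(Sigma_P[0, 0] - 1.0) > 1e-12:
        raise ValueError("the theta variance Sigma_P[0, 0] must equal 1")
    if Sigma_P[0, 1] != Sigma_P[1, 0]:
        raise ValueError("Sigma_P must be symmetric")
    if np.any(np.linalg.eigvalsh(Sigma_P) <= 0):
        raise ValueError("Sigma_P must be positive definite")
    return Sigma_P


@dataclass
class GeneratingSpec:
    """Hyper-level description of a generative run.

    ``mu_I``/``Sigma_I`` parameterize the normal distribution of the
    per-item vector (accuracy coefficients, xi); sigma_i is drawn
    log-normally from (``log_sigma_mu``, ``log_sigma_sd``) so that it is
    positive without truncation.
    """

    model: ModelSpec
    n_persons: int
    n_items: int
    Sigma_P: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.3], [0.3, 0.25]]))
    mu_I: np.ndarray | None = None
    Sigma_I: np.ndarray | None = None
    log_sigma_mu: float = np.log(0.4)
    log_sigma_sd: float = 0.15

    def __post_init__(self):
        self.Sigma_P = _check_sigma_p(self.Sigma_P)
        d = self.model.n_acc_params + 1
        if self.mu_I is None:
            mu = np.zeros(d)
            mu[0] = 1.0  # baseline slope
            self.mu_I = mu
        self.mu_I = np.asarray(self.mu_I, dtype=float)
        if self.Sigma_I is None:
            self.Sigma_I = np.eye(d) * 0.09
        self.Sigma_I = np.asarray(self.Sigma_I, dtype=float)
        if self.mu_I.shape != (d,) or self.Sigma_I.shape != (d, d):
            raise ValueError(
                f"item hyper-parameters must have dimension {d} for kind "
                f"{self.model.kind!r}")
        if np.any(np.linalg.eigvalsh(self.Sigma_I) < -1e-10):
            raise ValueError("Sigma_I must be positive semi-definite")


def sample_persons(n: int, Sigma_P: np.ndarray, seed) -> PersonSample:
    """Draw n independent (theta, tau) pairs from N2(0, Sigma_P)."""
    Sigma_P = _check_sigma_p(Sigma_P)
    rng = _as_rng(seed)
    L = np.linalg.cholesky(Sigma_P)
    raw = rng.standard_normal((n, 2)) @ L.T
    return PersonSample(theta=raw[:, 0], tau=raw[:, 1], Sigma_P=Sigma_P)


def sample_items(spec: GeneratingSpec, seed) -> ItemSample:
    """Draw item parameter vectors from the hyper distribution."""
    rng = _as_rng(seed)
    d = spec.model.n_acc_params
    v = rng.multivariate_normal(spec.mu_I, spec.Sigma_I, size=spec.n_items,
                                method="cholesky")
    sigma = np.exp(spec.log_sigma_mu + spec.log_sigma_sd
                   * rng.standard_normal(spec.n_items))
    return ItemSample(A=v[:, :d], xi=v[:, d], sigma=sigma)


def simulate_times(persons: PersonSample, xi: np.ndarray, sigma: np.ndarray,
                   seed) -> np.ndarray:
    """Log-normal response times: ln t_pi ~ N(xi_i - tau_p, sigma_i^2)."""
    xi = np.asarray(xi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("all sigma_i must be positive")
    rng = _as_rng(seed)
    eps = rng.standard_normal((persons.n, len(xi)))
    return np.exp(xi[None, :] - persons.tau[:, None] + sigma[None, :] * eps)


def true_residuals(T: np.ndarray, persons: PersonSample, xi: np.ndarray,
                   sigma: np.ndarray) -> np.ndarray:
    """Standardized residual log time under the generating parameters."""
    xi = np.asarray(xi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return (np.log(np.asarray(T, dtype=float)) - (xi[None, :] - persons.tau[:, None])) \
        / sigma[None, :]


def simulate_accuracy(model: ModelSpec, persons: PersonSample, items: ItemSample,
                      Z: np.ndarray, seed) -> np.ndarray:
    """Bernoulli accuracies with the model-appropriate probit probability."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (persons.n, items.k):
        raise ValueError("residual matrix shape does not match persons/items")
    s, c = model.slope_intercept(items.A, Z)
    prob = _phi(s * persons.theta[:, None] + c)
    rng = _as_rng(seed)
    return (rng.random(Z.shape) < prob).astype(np.int8)


def simulate_dataset(spec: GeneratingSpec, seed, items: ItemSample | None = None,
                     persons: PersonSample | None = None):
    """Full generative run; returns (Dataset, truth dict).

    Explicit ``items``/``persons`` override the hierarchical draws so that
    recovery studies can fix the ground truth.
    """
    root = _as_rng(seed)
    streams = root.spawn(4)
    if persons is None:
        persons = sample_persons(spec.n_persons, spec.Sigma_P, streams[0])
    if items is None:
        items = sample_items(spec, streams[1])
    T = simulate_times(persons, items.xi, items.sigma, streams[2])
    Z = true_residuals(T, persons, items.xi, items.sigma)
    X = simulate_accuracy(spec.model, persons, items, Z, streams[3])
    truth = {
        "model": spec.model.kind,
        "thresholds": list(spec.model.thresholds),
        "baseline": spec.model.baseline,
        "Sigma_P": np.asarray(spec.Sigma_P).tolist(),
        "A": items.A.tolist(),
        "xi": items.xi.tolist(),
        "sigma": items.sigma.tolist(),
        "theta": persons.theta.tolist(),
        "tau": persons.tau.tolist(),
    }
    return Dataset(X=X, T=T), truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
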