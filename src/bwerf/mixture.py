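"""1-D Gaussian mixture fitting by EM over unified importance values.

The unified importances of the TF pool are modeled as i.i.d. draws from a
finite mixture of K > 1 Gaussians,

    g(x_i) = sum_k alpha_k * phi(x_i; mu_k, sigma2_k),

and the putative regulators are the TFs whose posterior membership is
maximal for the component with the largest mean. The E-step computes the
membership weights

    w_ik = alpha_k phi_k(x_i) / sum_l alpha_l phi_l(x_i)

(in log space for stability) and the M-step the closed-form updates

    N_k = sum_i w_ik,   alpha_k = N_k / N,
    mu_k = sum_i w_ik x_i / N_k,
    sigma2_k = sum_i w_ik (x_i - mu_k)^2 / N_k,

with variances floored to avoid singular collapse on tied values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import ValidationError


@dataclass
class MixtureModel:
    """Parameters Theta = (alpha_k, mu_k, sigma2_k) of a K-component mixture."""

    alphas: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        k = self.alphas.shape[0]
        if k < 2:
            raise ValidationError("a mixture needs K > 1 components")
        if self.means.shape != (k,) or self.variances.shape != (k,):
            raise ValidationError("parameter vectors must share length K")
        if np.any(self.alphas <= 0) or not np.isclose(self.alphas.sum(), 1.0):
            raise ValidationError("mixing proportions must be positive and sum to 1")
        if np.any(self.variances <= 0):
            raise ValidationError("variances must be positive")

    @property
    def K(self) -> int:
        return self.alphas.shape[0]


@dataclass
class EMResult:
    model: MixtureModel
    log_likelihood: float
    log_likelihood_trace: list[float]
    n_iter: int
    converged: bool


def _log_densities(values: np.ndarray, model: MixtureModel) -> np.ndarray:
    """(N, K) matrix of log(alpha_k) + log phi_k(x_i)."""
    x = values[:, None]
    var = model.variances[None, :]
    mu = model.means[None, :]
    return (
        np.log(model.alphas)[None, :]
        - 0.5 * np.log(2 * np.pi * var)
        - 0.5 * (x - mu) ** 2 / var
    )


def log_likelihood(values: np.ndarray, model: MixtureModel) -> float:
    return float(logsumexp(_log_densities(np.asarray(values, float), model), axis=1).sum())


def e_step(values: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Posterior membership weights w_ik; each row sums to 1."""
    values = np.asarray(values, dtype=float)
    logd = _log_densities(values, model)
    return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))


def m_step(
    values: np.ndarray, weights: np.ndarray, var_floor: float | None = None
) -> MixtureModel:
    """Closed-form parameter updates from membership weights."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != values.shape[0]:
        raise ValidationError("weights must be N x K")
    if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("membership-weight rows must sum to 1")
    n_k = weights.sum(axis=0)
    if var_floor is None:
        var_floor = 1e-8 * max(values.var(), np.finfo(float).tiny)
    empty = n_k <= 1e-10
    if empty.any():
        # re-seed dead components at the least-claimed points
        weights = weights.copy()
        totals = weights.sum(axis=1)
        for k in np.flatnonzero(empty):
            i = int(np.argmin(totals))
            weights[i, :] = 0.0
            weights[i, k] = 1.0
            totals[i] = np.inf
        n_k = weights.sum(axis=0)
    alphas = n_k / values.shape[0]
    means = weights.T @ values / n_k
    var = (weights * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / n_k
    var = np.maximum(var, var_floor)
    return MixtureModel(alphas / alphas.sum(), means, var)


def _init_model(values: np.ndarray, K: int, rng: np.random.Generator | None) -> MixtureModel:
    """Quantile seeding: component k at the (k - 0.5)/K quantile, global
    variance, uniform mixing; random restarts jitter the means."""
    q = (np.arange(K) + 0.5) / K
    means = np.quantile(values, q)
    spread = values.std()
    if spread == 0:
        spread = 1.0
    if rng is not None:
        means = means + rng.normal(0.0, 0.25 * spread, size=K)
    var = max(values.var(), 1e-8 * spread**2, np.finfo(float).tiny)
    return MixtureModel(np.full(K, 1.0 / K), means, np.full(K, var))


def em_fit(
    values: np.ndarray,
    K: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    restarts: int = 5,
    seed: int = 0,
) -> EMResult:
    """Fit a K-component mixture by EM; best log-likelihood over restarts.

    The first run starts from the deterministic quantile initialization;
    each restart jitters the seeded means. Convergence is declared when the
    log-likelihood improves by less than ``tol``.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.shape[0]
    if n < 2 * K:
        raise ValidationError(f"need at least 2K = {2 * K} values, got {n}")
    var_floor = 1e-8 * max(values.var(), np.finfo(float).tiny)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best: EMResult | None = None
    for r in range(restarts + 1):
        model = _init_model(values, K, rng if r > 0 else None)
        trace: list[float] = [log_likelihood(values, model)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = e_step(values, model)
            model = m_step(values, w, var_floor=var_floor)
            ll = log_likelihood(values, model)
            trace.append(ll)
            if abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        result = EMResult(model, trace[-1], trace, it, converged)
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def extract_top_component(values: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Boolean mask: membership argmax equals the largest-mean component.

    Tied maximal means are broken toward the lower component index; the
    responsibility argmax likewise takes the first maximal component.
    """
    values = np.asarray(values, dtype=float)
    top = int(np.argmax(model.means))
    w = e_step(values, model)
    return w.argmax(axis=1) == top
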