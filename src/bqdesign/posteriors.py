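"""Conjugate posterior inference for toxicity and efficacy.

Toxicity at each dose is binary with a beta-binomial model, so the
posterior of the toxicity rate pi_j is Beta(m_j + a, n_j - m_j + b).

Efficacy is handled through a quasi-Bernoulli likelihood: the outcome is
standardized onto [0, 1] and treated *as if* Bernoulli, so that the
standardized conditional mean theta_jk = E(y* | x = k, dose j) also gets a
conjugate Beta posterior, Beta(s_jk + a, n_jk - s_jk + b), where the
"pseudo-event" sum s_jk may be fractional.  This one device covers binary,
ordinal and (bounded) continuous endpoints without any parametric
dose-response model.

Marginal mean-efficacy draws on the original scale follow by mixing the
two toxicity strata draw-by-draw:

    mu_j(t) = pi_j(t) * g_j^{-1}(theta_j1(t)) + (1 - pi_j(t)) * g_j^{-1}(theta_j0(t))

with g_j the dose-specific standardization map.  Monotonization across
doses (weighted PAVA per draw) is applied afterwards to the pi draws and,
optionally, to the mu draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .config import DesignConfig
from .data import BetaParams, TrialData
from .isotonic import isotonize_draws, posterior_variance_weights

__all__ = [
    "PosteriorDraws",
    "toxicity_posterior",
    "efficacy_posterior",
    "standardize_efficacy",
    "inverse_standardize",
    "sample_posterior",
    "clopper_pearson",
]


@dataclass
class PosteriorDraws:
    """Matched Monte-Carlo posterior draws across all doses.

    All matrices are T x J.  ``pi`` are toxicity-rate draws, ``theta0`` and
    ``theta1`` standardized conditional-efficacy draws in the no-toxicity /
    toxicity strata, and ``mu`` marginal mean-efficacy draws on the
    original endpoint scale.  When isotonization is enabled, ``pi`` (and
    ``mu``) rows are non-decreasing in dose.
    """

    pi: np.ndarray
    theta0: np.ndarray
    theta1: np.ndarray
    mu: np.ndarray
    bounds: np.ndarray  # J x 2 standardization bounds used for g^{-1}

    @property
    def n_draws(self) -> int:
        return self.pi.shape[0]

    @property
    def n_arms(self) -> int:
        return self.pi.shape[1]


def toxicity_posterior(data: TrialData, prior: BetaParams, dose: int) -> BetaParams:
    """Beta posterior of the toxicity rate at ``dose`` (1-based)."""
    if not 1 <= dose <= data.n_arms:
        raise ValueError(f"dose {dose} out of range 1..{data.n_arms}")
    n, m = data.toxicity_counts()
    j = dose - 1
    return BetaParams(m[j] + prior.alpha, n[j] - m[j] + prior.beta)


def efficacy_posterior(data: TrialData, prior: BetaParams, dose: int, tox_level: int) -> BetaParams:
    """Beta posterior of the standardized conditional efficacy mean.

    ``tox_level`` selects the stratum of patients with toxicity outcome
    0 or 1; the pseudo-event sum may be fractional for non-binary
    endpoints.
    """
    if not 1 <= dose <= data.n_arms:
        raise ValueError(f"dose {dose} out of range 1..{data.n_arms}")
    if tox_level not in (0, 1):
        raise ValueError("tox_level must be 0 or 1")
    n_jk, s_jk = data.efficacy_strata()
    j = dose - 1
    return BetaParams(s_jk[j, tox_level] + prior.alpha,
                      n_jk[j, tox_level] - s_jk[j, tox_level] + prior.beta)


def standardize_efficacy(y, bounds: tuple[float, float]):
    """Map an efficacy value onto [0, 1] given (lower, upper) bounds."""
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("degenerate standardization bounds (upper <= lower)")
    return (np.asarray(y, dtype=float) - lo) / (hi - lo)


def inverse_standardize(theta, bounds: tuple[float, float]):
    """Inverse of :func:`standardize_efficacy`: back to the original scale."""
    lo, hi = bounds
    return np.asarray(theta, dtype=float) * (hi - lo) + lo


def sample_posterior(
    data: TrialData,
    config: DesignConfig,
    n_draws: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> PosteriorDraws:
    """Draw T matched posterior samples of (pi, theta0, theta1, mu) per dose.

    Draws are sampled independently across doses and strata from the
    conjugate Beta posteriors, the marginal mean-efficacy draws are formed
    by mixing the strata through the dose-specific inverse standardization
    map, and the configured monotonizations are applied last.
    """
    T = config.n_draws if n_draws is None else int(n_draws)
    if T < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(rng)
    J = data.n_arms

    n, m = data.toxicity_counts()
    bounds = data.standardization_bounds()
    n_jk, s_jk = data.efficacy_strata(bounds)

    at = config.tox_prior.alpha + m
    bt = config.tox_prior.beta + (n - m)
    pi = rng.beta(at, bt, size=(T, J))

    a0 = config.eff_prior.alpha + s_jk[:, 0]
    b0 = config.eff_prior.beta + (n_jk[:, 0] - s_jk[:, 0])
    a1 = config.eff_prior.alpha + s_jk[:, 1]
    b1 = config.eff_prior.beta + (n_jk[:, 1] - s_jk[:, 1])
    theta0 = rng.beta(a0, b0, size=(T, J))
    theta1 = rng.beta(a1, b1, size=(T, J))

    span = bounds[:, 1] - bounds[:, 0]
    degenerate = span <= 0
    if degenerate.any():
        # no spread anywhere in the data: the map carries no information
        theta0 = theta0.copy()
        theta1 = theta1.copy()
        theta0[:, degenerate] = 0.5
        theta1[:, degenerate] = 0.5
    lo = bounds[:, 0]
    y1 = theta1 * span + lo  # g^{-1} per dose, broadcast over draws
    y0 = theta0 * span + lo
    mu = pi * y1 + (1.0 - pi) * y0

    if config.isotonic_toxicity:
        pi = isotonize_draws(pi, posterior_variance_weights(pi))
    if config.isotonic_efficacy:
        mu = isotonize_draws(mu, posterior_variance_weights(mu))
    return PosteriorDraws(pi=pi, theta0=theta0, theta1=theta1, mu=mu, bounds=bounds)


def clopper_pearson(events: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a rate."""
    lo, hi = proportion_confint(events, trials, alpha=1.0 - level, method="beta")
    return float(lo), float(hi)
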