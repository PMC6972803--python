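"""Kuo-Mallick spike-and-slab regression level.

The focal species' log-relative abundance a_bj is modelled as

    a_bj ~ Normal(mu_j, precision tau),
    mu_j = a0 + sum_r gamma_r * beta_r * X_jr,

where X is the standardized J x R covariate matrix, gamma_r in {0, 1} is a
Bernoulli(0.5) inclusion indicator and beta_r a regression coefficient with
a vague Normal(0, precision 0.01) prior (sd 10).  All Normal distributions
in this module are parameterized by *precision* (inverse variance), the
convention of the Gibbs-sampling software this class of models is normally
fitted with; tau carries a Uniform(0.0001, 1000) prior on the precision
scale.

The module exposes the full conditionals of the Gibbs sweep over
(gamma, beta, a0, tau) given a_b.  Under the Kuo-Mallick scheme an excluded
coefficient (gamma_r = 0) is refreshed from its prior — the "detached" draw
— which is what lets the indicator re-enter the model later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaincinv

from .errors import BadDimension, BadIndex

__all__ = [
    "SelectionState",
    "BETA_PRIOR_PRECISION",
    "A0_PRIOR_PRECISION",
    "GAMMA_PRIOR_PROB",
    "TAU_SUPPORT",
    "regression_mean",
    "gamma_full_conditional",
    "draw_beta_conditional",
    "draw_a0_conditional",
    "draw_tau_conditional",
]

#: prior precision of each regression coefficient beta_r (sd 10)
BETA_PRIOR_PRECISION: float = 0.01
#: prior precision of the intercept a0
A0_PRIOR_PRECISION: float = 0.01
#: prior inclusion probability of each covariate
GAMMA_PRIOR_PROB: float = 0.5
#: support of the Uniform prior on the noise precision tau
TAU_SUPPORT: tuple[float, float] = (0.0001, 1000.0)


@dataclass
class SelectionState:
    """Current state of the regression level: (gamma, beta, a0, tau).

    tau may momentarily sit outside the Uniform prior support (the joint
    posterior density is simply -inf there); the tau sampler never leaves
    the support.
    """

    gamma: np.ndarray             # (R,) of {0, 1}
    beta: np.ndarray              # (R,)
    a0: float
    tau: float

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.gamma.shape != self.beta.shape or self.gamma.ndim != 1:
            raise BadDimension("gamma and beta must be 1-d of equal length")
        if not np.all((self.gamma == 0) | (self.gamma == 1)):
            raise ValueError("gamma entries must be 0 or 1")
        if self.tau <= 0:
            raise ValueError("tau is a precision and must be positive")

    @property
    def R(self) -> int:
        return self.gamma.shape[0]

    def copy(self) -> "SelectionState":
        return SelectionState(self.gamma.copy(), self.beta.copy(), self.a0, self.tau)


def _design(X) -> np.ndarray:
    M = X.X if hasattr(X, "X") else np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise BadDimension("X must be a J x R matrix")
    return M


def regression_mean(state: SelectionState, X) -> np.ndarray:
    """mu_j = a0 + sum_r gamma_r beta_r X_jr."""
    M = _design(X)
    if M.shape[1] != state.R:
        raise BadDimension(f"X has {M.shape[1]} columns but state has R={state.R}")
    return state.a0 + M @ (state.gamma * state.beta)


def _partial_residual(r: int, state: SelectionState, a_b: np.ndarray, M: np.ndarray):
    """a_b minus every regression term except covariate r's own."""
    if not 0 <= r < state.R:
        raise BadIndex(f"covariate index {r} out of range for R={state.R}")
    mu = regression_mean(state, M)
    resid = np.asarray(a_b, dtype=float) - mu
    if resid.shape != (M.shape[0],):
        raise BadDimension("a_b must have one entry per unit")
    return resid + state.gamma[r] * state.beta[r] * M[:, r]


def gamma_full_conditional(r: int, state: SelectionState, a_b: np.ndarray, X) -> float:
    """Posterior probability that gamma_r = 1, beta_r held at its value.

    The Bernoulli(0.5) prior cancels, leaving the Normal likelihood ratio of
    a_b under mu computed with the r-th term switched on versus off;
    evaluated on the log scale.
    """
    M = _design(X)
    resid = _partial_residual(r, state, a_b, M)
    x = M[:, r]
    b = state.beta[r]
    # log LR = -tau/2 [ sum(resid - b x)^2 - sum(resid)^2 ]
    log_odds = state.tau * (b * float(x @ resid) - 0.5 * b * b * float(x @ x))
    log_odds += np.log(GAMMA_PRIOR_PROB) - np.log1p(-GAMMA_PRIOR_PROB)
    if log_odds >= 0:
        return float(1.0 / (1.0 + np.exp(-log_odds)))
    e = np.exp(log_odds)
    return float(e / (1.0 + e))


def draw_beta_conditional(
    r: int, state: SelectionState, a_b: np.ndarray, X, rng: np.random.Generator
) -> float:
    """Draw beta_r from its full conditional.

    Excluded (gamma_r = 0): the Kuo-Mallick detached draw from the prior
    Normal(0, precision 0.01).  Included: the conjugate Normal combining the
    prior with the data precision tau * sum_j X_jr^2 given the partial
    residuals.
    """
    M = _design(X)
    if state.gamma[r] == 0:
        _partial_residual(r, state, a_b, M)  # validates r and shapes
        return float(rng.normal(0.0, 1.0 / np.sqrt(BETA_PRIOR_PRECISION)))
    resid = _partial_residual(r, state, a_b, M)
    x = M[:, r]
    prec = BETA_PRIOR_PRECISION + state.tau * float(x @ x)
    mean = state.tau * float(x @ resid) / prec
    return float(rng.normal(mean, 1.0 / np.sqrt(prec)))


def draw_a0_conditional(
    state: SelectionState, a_b: np.ndarray, X, rng: np.random.Generator
) -> float:
    """Conjugate draw of the intercept under its Normal(0, 0.01) prior."""
    M = _design(X)
    resid = np.asarray(a_b, dtype=float) - M @ (state.gamma * state.beta)
    J = M.shape[0]
    prec = A0_PRIOR_PRECISION + state.tau * J
    mean = state.tau * float(resid.sum()) / prec
    return float(rng.normal(mean, 1.0 / np.sqrt(prec)))


def _truncated_gamma_icdf(shape: float, rate: float, lo: float, hi: float, u: float) -> float:
    """Inverse CDF at u of a Gamma(shape, rate) truncated to [lo, hi].

    Falls back to an exponential-tilt approximation when the Gamma places
    numerically zero mass inside the interval (e.g. SSR -> 0 pushes the
    conditional against the upper bound).
    """
    if rate > 0:
        f_lo = gammainc(shape, rate * lo)
        f_hi = gammainc(shape, rate * hi)
        if f_hi - f_lo > 1e-14:
            x = gammaincinv(shape, f_lo + u * (f_hi - f_lo)) / rate
            return float(min(max(x, lo), hi))
    else:
        # SSR = 0: density ∝ t^(shape-1) on [lo, hi]; exact power-law
        # inverse CDF, computed in logs ((lo/hi)^shape underflows to 0)
        return float(hi * math.exp(math.log(u) / shape)) if u > 0 else lo
    # density ∝ exp((shape-1) log t - rate t): linearize the log density at
    # the boundary the mass leans against
    anchor = hi if rate == 0 or shape / max(rate, 1e-300) > hi else lo
    c = (shape - 1.0) / anchor - rate
    span = hi - lo
    if abs(c) * span < 1e-12:
        return lo + u * span
    if c > 0:
        # increasing density; work from the upper bound for stability
        t = hi + np.log(u + (1.0 - u) * np.exp(-min(c * span, 700.0))) / c
    else:
        t = lo + np.log1p(u * np.expm1(max(c * span, -700.0))) / c
    return float(min(max(t, lo), hi))


def draw_tau_conditional(
    state: SelectionState, a_b: np.ndarray, X, rng: np.random.Generator
) -> float:
    """Draw tau from its full conditional under the Uniform(0.0001, 1000) prior.

    The conditional is Gamma(shape J/2 + 1, rate SSR/2) truncated to the
    prior support, with SSR = sum_j (a_bj - mu_j)^2; sampled by inverse CDF
    on the truncated region.
    """
    M = _design(X)
    mu = regression_mean(state, M)
    resid = np.asarray(a_b, dtype=float) - mu
    ssr = float(resid @ resid)
    J = M.shape[0]
    lo, hi = TAU_SUPPORT
    return _truncated_gamma_icdf(J / 2.0 + 1.0, ssr / 2.0, lo, hi, float(rng.uniform()))
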