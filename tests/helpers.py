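"""Shared statistical helpers for the test suite."""

import numpy as np
from scipy.stats import multivariate_normal

from abundsel.selection_model import (
    A0_PRIOR_PRECISION,
    BETA_PRIOR_PRECISION,
    GAMMA_PRIOR_PROB,
)


def batch_mean_se(x: np.ndarray, n_batches: int = 30) -> float:
    """Monte-Carlo standard error of mean(x) by batch means (autocorrelation-robust)."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x) // n_batches * n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def enumerate_model_probabilities(y: np.ndarray, X: np.ndarray, tau: float) -> dict:
    """Exact posterior model probabilities by conjugate enumeration.

    For fixed noise precision tau, each inclusion pattern gamma has marginal
    likelihood m(y | gamma) with (a0, active betas) integrated out under
    their Normal(0, 0.01) priors:

        y | gamma ~ N(0, I/tau + Z D Z^T),  Z = [1, X_active], D = 100 I.

    Returns {pattern string: probability} over all 2^R patterns (uniform
    pattern prior, so the Bernoulli(0.5) prior factors cancel).
    """
    J, R = X.shape
    assert GAMMA_PRIOR_PROB == 0.5  # uniform over patterns
    logm = {}
    for bits in range(2**R):
        gamma = [(bits >> r) & 1 for r in range(R)]
        Z = np.column_stack(
            [np.ones(J)] + [X[:, r] for r in range(R) if gamma[r]]
        )
        prior_var = np.diag(
            [1.0 / A0_PRIOR_PRECISION] + [1.0 / BETA_PRIOR_PRECISION] * (Z.shape[1] - 1)
        )
        cov = np.eye(J) / tau + Z @ prior_var @ Z.T
        pattern = "".join(str(g) for g in gamma)
        logm[pattern] = multivariate_normal.logpdf(y, mean=np.zeros(J), cov=cov)
    shift = max(logm.values())
    weights = {k: np.exp(v - shift) for k, v in logm.items()}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}
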