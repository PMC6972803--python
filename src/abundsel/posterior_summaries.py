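"""Posterior summaries: inclusion probabilities, model table, final refit,
and the [0, 1] relative-abundance index.

The selection run yields draws of the indicator vector gamma.  From these,
``inclusion_probabilities`` gives each covariate's posterior probability of
belonging to the model, and ``model_probabilities`` the posterior
probability of every visited gamma-pattern (the "model table"; the best
model is the pattern the chains visited most often).  Covariates with
p_r above the 0.5 threshold are then refitted with gamma frozen
(``select_and_refit``), yielding posterior means and equal-tailed 95%
credible intervals for the retained coefficients; the refit's per-unit
posterior means of focal log-relative abundance are min-max rescaled into
the final [0, 1] abundance index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateRange, EmptyDraws
from .mcmc_engine import McmcConfig, PosteriorDraws, run_mcmc

__all__ = [
    "InclusionSummary",
    "ModelTable",
    "FinalFit",
    "AbundanceIndex",
    "inclusion_probabilities",
    "model_probabilities",
    "select_and_refit",
    "abundance_index",
]


def _require_draws(draws: PosteriorDraws) -> None:
    if draws.gamma.size == 0 or draws.n_keep == 0:
        raise EmptyDraws("no retained posterior draws")


@dataclass
class InclusionSummary:
    """Posterior inclusion probability p_r per covariate, with ranks."""

    covariate_names: list[str]
    p: np.ndarray                 # (R,) in [0, 1]

    @property
    def rank(self) -> np.ndarray:
        """1 = highest p_r."""
        order = np.argsort(-self.p, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(self.p) + 1)
        return ranks

    def selected(self, threshold: float = 0.5) -> list[str]:
        """Covariates with p_r strictly above the threshold."""
        return [n for n, p in zip(self.covariate_names, self.p) if p > threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.covariate_names, "p_r": self.p, "rank": self.rank}
        ).sort_values("rank", ignore_index=True)


@dataclass
class ModelTable:
    """Posterior probability of each visited gamma-pattern.

    Patterns are bit strings in covariate order ('1011' = covariates 1, 3
    and 4 in the model).  Probabilities are visit frequencies over all
    pooled draws; they sum to 1 and only visited patterns appear.
    """

    covariate_names: list[str]
    patterns: list[str]           # sorted by decreasing probability
    probabilities: np.ndarray

    @property
    def best(self) -> str:
        """The most often visited pattern."""
        return self.patterns[0]

    def pattern_terms(self, pattern: str) -> list[str]:
        return [n for n, bit in zip(self.covariate_names, pattern) if bit == "1"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern": self.patterns,
                "terms": [" + ".join(self.pattern_terms(p)) or "(intercept only)"
                          for p in self.patterns],
                "probability": self.probabilities,
            }
        )


def inclusion_probabilities(draws: PosteriorDraws) -> InclusionSummary:
    """p_r = fraction of pooled retained draws with gamma_r = 1."""
    _require_draws(draws)
    return InclusionSummary(
        covariate_names=list(draws.covariate_names),
        p=draws.pooled("gamma").mean(axis=0),
    )


def model_probabilities(draws: PosteriorDraws) -> ModelTable:
    """Visit frequency of every gamma-pattern, sorted by probability."""
    _require_draws(draws)
    g = draws.pooled("gamma")
    patterns, counts = np.unique(g, axis=0, return_counts=True)
    probs = counts / g.shape[0]
    order = np.argsort(-probs, kind="stable")
    return ModelTable(
        covariate_names=list(draws.covariate_names),
        patterns=["".join(str(int(b)) for b in patterns[i]) for i in order],
        probabilities=probs[order],
    )


@dataclass
class FinalFit:
    """Refit with the selected covariates forced in and the rest out.

    ``table`` columns mirror the study's coefficient table: variable, p_r
    from the selection run, posterior mean beta_r, and the equal-tailed
    95% credible interval, for the retained covariates only.
    """

    selected: list[str]
    table: pd.DataFrame
    a0_mean: float
    a0_interval: tuple[float, float]
    tau_mean: float
    tau_interval: tuple[float, float]
    threshold: float
    draws: PosteriorDraws         # draws of the frozen-gamma refit


def _mean_and_interval(x: np.ndarray, level: float = 0.95):
    lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(x.mean()), (float(lo), float(hi))


def select_and_refit(
    draws: PosteriorDraws,
    data,
    X,
    threshold: float = 0.5,
    config: McmcConfig | None = None,
    a_b_fixed: np.ndarray | None = None,
) -> FinalFit:
    """Freeze gamma at the selected pattern and refit.

    Covariates with selection-run p_r strictly above ``threshold`` are set
    to gamma_r = 1, all others to 0, and the model is resampled with no
    indicator updates (an intercept-only refit if nothing is selected).
    ``config`` defaults to the selection run's own protocol.
    """
    incl = inclusion_probabilities(draws)
    frozen = (incl.p > threshold).astype(np.int64)
    cfg = config if config is not None else draws.config
    if cfg is None:
        raise ValueError("no MCMC configuration available for the refit")
    cfg = replace(cfg, frozen_gamma=frozen)
    refit = run_mcmc(data, X, cfg, a_b_fixed=a_b_fixed)

    names = list(draws.covariate_names)
    rows = []
    beta = refit.pooled("beta")
    for r, name in enumerate(names):
        if frozen[r]:
            mean, (lo, hi) = _mean_and_interval(beta[:, r])
            rows.append({"variable": name, "p_r": float(incl.p[r]),
                         "beta_mean": mean, "ci_low": lo, "ci_high": hi})
    a0_mean, a0_ci = _mean_and_interval(refit.pooled("a0"))
    tau_mean, tau_ci = _mean_and_interval(refit.pooled("tau"))
    return FinalFit(
        selected=[names[r] for r in range(len(names)) if frozen[r]],
        table=pd.DataFrame(rows, columns=["variable", "p_r", "beta_mean", "ci_low", "ci_high"]),
        a0_mean=a0_mean,
        a0_interval=a0_ci,
        tau_mean=tau_mean,
        tau_interval=tau_ci,
        threshold=threshold,
        draws=refit,
    )


@dataclass
class AbundanceIndex:
    """Per-unit relative-abundance index on [0, 1].

    ``index`` is the min-max rescaling of ``posterior_mean`` (the posterior
    mean of focal log-relative abundance a_bj); the least abundant unit
    maps to 0 and the most abundant to 1.
    """

    unit_ids: np.ndarray
    index: np.ndarray
    posterior_mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_ids, "index": self.index})


def abundance_index(draws: PosteriorDraws | FinalFit) -> AbundanceIndex:
    """Min-max rescale the posterior mean log-relative abundances to [0, 1]."""
    if isinstance(draws, FinalFit):
        draws = draws.draws
    _require_draws(draws)
    m = draws.pooled("a_b").mean(axis=0)
    span = m.max() - m.min()
    if m.size < 2 or span == 0:
        raise DegenerateRange("all posterior means equal; index undefined")
    return AbundanceIndex(
        unit_ids=draws.unit_ids,
        index=(m - m.min()) / span,
        posterior_mean=m,
    )
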