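"""Joint posterior sampling by Metropolis-within-Gibbs.

One sweep updates, in order:

1. every observation-level free parameter (a_ij, e_j2, p_i2) by element-wise
   random-walk Metropolis — valid as a simultaneous block because, given the
   other blocks, the Poisson likelihood factorizes over the updated elements;
   the focal species' a_bj Metropolis ratio includes its Normal(mu_j, tau)
   regression prior, all other elements carry vague Normal(0, precision
   0.01) priors;
2. the intercept a0 and each (gamma_r, beta_r) pair by their conjugate /
   Kuo-Mallick full conditionals;
3. the noise precision tau by inverse-CDF from its truncated-Gamma full
   conditional.

The default protocol runs three chains with a 1,000-sweep burn-in followed
by 300,000 recorded sweeps thinned by 100; ``quick_profile`` gives the
scaled-down 3 x (2,000 + 20,000, thin 10) profile used throughout the test
suite.  Proposal scales adapt per element toward a 0.35 acceptance rate
during burn-in only, so the post-burn-in kernel is fixed.

The sweep kernel is compiled with numba when available and falls back to
the identical pure-Python code path otherwise.  Each chain is seeded from
``seed + chain`` and runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .covariate_prep import CovariateMatrix
from .errors import BadDimension, NonFiniteState, SingleChain, UnitMismatch
from .observation_model import (
    ObservationParams,
    SurveyDataset,
    compute_log_intensity,
    survey_log_likelihood,
)
from .selection_model import (
    A0_PRIOR_PRECISION,
    BETA_PRIOR_PRECISION,
    GAMMA_PRIOR_PROB,
    TAU_SUPPORT,
    SelectionState,
    _truncated_gamma_icdf,
    draw_a0_conditional,
    draw_beta_conditional,
    draw_tau_conditional,
    gamma_full_conditional,
    regression_mean,
)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "AgreementReport",
    "quick_profile",
    "log_posterior",
    "run_mcmc",
    "check_chain_agreement",
]

logger = logging.getLogger(__name__)

#: prior precision of the nuisance observation-level parameters
#: (non-focal a_ij, e_j2, p_i2)
NUISANCE_PRIOR_PRECISION: float = 0.01


@dataclass
class McmcConfig:
    """Sampler protocol and tuning knobs.

    ``n_iter`` sweeps are recorded after ``n_burn`` unrecorded ones; every
    ``thin``-th state is retained, so each chain keeps n_iter / thin draws.
    ``fix_tau`` freezes the noise precision (used by the exact-enumeration
    cross-checks); ``frozen_gamma`` disables indicator updates and pins the
    inclusion pattern (used by the final refit).
    """

    n_chains: int = 3
    n_burn: int = 1_000
    n_iter: int = 300_000
    thin: int = 100
    seed: int = 0
    proposal_sd_a: float = 0.5
    proposal_sd_e: float = 0.2
    proposal_sd_p: float = 0.2
    adapt: bool = True
    adapt_target: float = 0.35
    adapt_window: int = 50
    focal_species: int | None = None
    fix_tau: float | None = None
    frozen_gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_burn, self.n_iter, self.thin) < 1:
            raise ValueError("chain, burn-in, iteration and thinning counts must be positive")
        if self.n_iter % self.thin:
            raise ValueError("thin must divide n_iter")
        if self.frozen_gamma is not None:
            self.frozen_gamma = np.asarray(self.frozen_gamma, dtype=np.int64)

    @property
    def n_keep(self) -> int:
        return self.n_iter // self.thin


def quick_profile(seed: int = 0, **overrides) -> McmcConfig:
    """Scaled-down sampling profile (3 chains x 20,000 sweeps, thin 10)."""
    cfg = McmcConfig(n_chains=3, n_burn=2_000, n_iter=20_000, thin=10, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class PosteriorDraws:
    """Thinned multi-chain samples of every parameter.

    Leading axes are (chain, draw).  ``a_b`` holds the focal species'
    log-relative abundances; ``e_alive`` and ``p_alive`` the nuisance
    effort/detectability offsets.  In regression-only runs (the observation
    level replaced by a fixed a_b) those nuisance arrays are empty.
    """

    gamma: np.ndarray             # (C, K, R) int
    beta: np.ndarray              # (C, K, R)
    a0: np.ndarray                # (C, K)
    tau: np.ndarray               # (C, K)
    a_b: np.ndarray               # (C, K, J)
    e_alive: np.ndarray           # (C, K, J) or (C, K, 0)
    p_alive: np.ndarray           # (C, K, I) or (C, K, 0)
    iterations: np.ndarray        # (K,) 1-based sweep index of each draw
    covariate_names: list[str]
    unit_ids: np.ndarray
    acceptance: dict = field(default_factory=dict)
    config: McmcConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_keep(self) -> int:
        return self.gamma.shape[1]

    @property
    def R(self) -> int:
        return self.gamma.shape[2]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter with the chain axis flattened away."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def to_frames(self):
        """One tidy DataFrame per chain (iteration + every scalar column)."""
        import pandas as pd

        frames = []
        for c in range(self.n_chains):
            cols = {"iteration": self.iterations}
            for r, name in enumerate(self.covariate_names):
                cols[f"gamma_{name}"] = self.gamma[c, :, r]
                cols[f"beta_{name}"] = self.beta[c, :, r]
            cols["a0"] = self.a0[c]
            cols["tau"] = self.tau[c]
            for j, uid in enumerate(self.unit_ids):
                cols[f"a_b_{uid}"] = self.a_b[c, :, j]
            frames.append(pd.DataFrame(cols))
        return frames


# --------------------------------------------------------------------------
# sweep kernel (numba-compiled when available)
# --------------------------------------------------------------------------

def _seed_kernel_py(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


def _sweep_py(
    counts, nsum, nal_j, nal_i, log_s, log_v,
    a, e2, p2, lam, X, gamma, beta, a0, tau, mu,
    focal, ref, sxx, update_obs, update_gamma,
    scale_a, scale_e, scale_p, acc_a, acc_e, acc_p,
    nuis_prec, beta_prec, a0_prec, gamma_logit,
):
    """One Metropolis-within-Gibbs sweep; mutates the state arrays in place.

    Returns (new a0, SSR) where SSR = sum_j (a_bj - mu_j)^2 evaluated after
    all updates, ready for the tau draw.
    """
    I, J = a.shape
    R = gamma.shape[0]
    if update_obs:
        # --- a_ij random-walk Metropolis (element-wise) ---
        for i in range(I):
            for j in range(J):
                d = scale_a[i, j] * np.random.normal()
                cur = a[i, j]
                lam_sum = lam[i, j, 0] + lam[i, j, 1]
                ed = math.exp(d)
                dll = nsum[i, j] * d - lam_sum * (ed - 1.0)
                if i == focal:
                    dm = cur - mu[j]
                    dll -= 0.5 * tau * (d * d + 2.0 * d * dm)
                else:
                    dll -= 0.5 * nuis_prec * (d * d + 2.0 * d * cur)
                if dll >= 0.0 or math.log(np.random.random()) < dll:
                    a[i, j] = cur + d
                    lam[i, j, 0] *= ed
                    lam[i, j, 1] *= ed
                    acc_a[i, j] += 1
        # --- e_j2 (alive-status effort) ---
        for j in range(J):
            d = scale_e[j] * np.random.normal()
            ed = math.exp(d)
            lam_sum = 0.0
            for i in range(I):
                lam_sum += lam[i, j, 1]
            dll = nal_j[j] * d - lam_sum * (ed - 1.0)
            dll -= 0.5 * nuis_prec * (d * d + 2.0 * d * e2[j])
            if dll >= 0.0 or math.log(np.random.random()) < dll:
                e2[j] += d
                for i in range(I):
                    lam[i, j, 1] *= ed
                acc_e[j] += 1
        # --- p_i2 (alive detectability offsets; reference fixed at 0) ---
        for i in range(I):
            if i == ref:
                continue
            d = scale_p[i] * np.random.normal()
            ed = math.exp(d)
            lam_sum = 0.0
            for j in range(J):
                lam_sum += lam[i, j, 1]
            dll = nal_i[i] * d - lam_sum * (ed - 1.0)
            dll -= 0.5 * nuis_prec * (d * d + 2.0 * d * p2[i])
            if dll >= 0.0 or math.log(np.random.random()) < dll:
                p2[i] += d
                for j in range(J):
                    lam[i, j, 1] *= ed
                acc_p[i] += 1
    # --- intercept a0 (conjugate) ---
    resid_sum = 0.0
    for j in range(J):
        resid_sum += a[focal, j] - (mu[j] - a0)
    prec = a0_prec + tau * J
    a0_new = (tau * resid_sum + math.sqrt(prec) * np.random.normal()) / prec
    for j in range(J):
        mu[j] += a0_new - a0
    a0 = a0_new
    # --- (gamma_r, beta_r) pairs: Kuo-Mallick ---
    for r in range(R):
        b_r = beta[r]
        g_r = gamma[r]
        sxr = 0.0
        for j in range(J):
            partial = a[focal, j] - mu[j] + g_r * b_r * X[j, r]
            sxr += X[j, r] * partial
        if update_gamma:
            log_odds = tau * (b_r * sxr - 0.5 * b_r * b_r * sxx[r]) + gamma_logit
            if log_odds > 0.0:
                p1 = 1.0 / (1.0 + math.exp(-log_odds))
            else:
                e = math.exp(log_odds)
                p1 = e / (1.0 + e)
            g_new = 1 if np.random.random() < p1 else 0
        else:
            g_new = g_r
        if g_new == 0:
            b_new = np.random.normal() / math.sqrt(beta_prec)
        else:
            bprec = beta_prec + tau * sxx[r]
            b_new = (tau * sxr + math.sqrt(bprec) * np.random.normal()) / bprec
        if g_new != g_r or b_new != b_r:
            for j in range(J):
                mu[j] += (g_new * b_new - g_r * b_r) * X[j, r]
            gamma[r] = g_new
            beta[r] = b_new
    ssr = 0.0
    for j in range(J):
        dmj = a[focal, j] - mu[j]
        ssr += dmj * dmj
    return a0, ssr


try:  # compile the kernel when numba is present; plain Python otherwise
    from numba import njit

    _sweep = njit(cache=True)(_sweep_py)
    _seed_kernel = njit(cache=True)(_seed_kernel_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _sweep = _sweep_py
    _seed_kernel = _seed_kernel_py


# --------------------------------------------------------------------------
# joint posterior density (used by oracle tests, not by the sampler loop)
# --------------------------------------------------------------------------

def log_posterior(
    obs_params: ObservationParams,
    sel_state: SelectionState,
    data: SurveyDataset,
    X,
) -> float:
    """Unnormalized log posterior of the full two-level model.

    Sum of the Poisson survey log likelihood, the Normal(mu, tau) density
    of the focal row of ``obs_params.a``, and every prior: Bernoulli(0.5)
    on gamma, Normal(0, 0.01) on beta and a0, Uniform on tau (-inf outside
    its support) and Normal(0, 0.01) on the nuisance observation
    parameters.
    """
    lo, hi = TAU_SUPPORT
    if not lo <= sel_state.tau <= hi:
        return -np.inf
    ll = survey_log_likelihood(obs_params, data)
    a_b = obs_params.a[data.focal]
    mu = regression_mean(sel_state, X)
    lp = float(np.sum(norm.logpdf(a_b, mu, 1.0 / np.sqrt(sel_state.tau))))
    # selection-level priors
    lp += float(
        sel_state.R * np.log(GAMMA_PRIOR_PROB)  # Bernoulli(0.5): same mass either way
    )
    lp += float(np.sum(norm.logpdf(sel_state.beta, 0.0, 1.0 / np.sqrt(BETA_PRIOR_PRECISION))))
    lp += float(norm.logpdf(sel_state.a0, 0.0, 1.0 / np.sqrt(A0_PRIOR_PRECISION)))
    lp += -np.log(hi - lo)
    # nuisance priors
    sd_n = 1.0 / np.sqrt(NUISANCE_PRIOR_PRECISION)
    mask = np.ones(data.I, dtype=bool)
    mask[data.focal] = False
    lp += float(np.sum(norm.logpdf(obs_params.a[mask], 0.0, sd_n)))
    lp += float(np.sum(norm.logpdf(obs_params.e_alive, 0.0, sd_n)))
    p_mask = np.ones(data.I, dtype=bool)
    p_mask[obs_params.reference] = False
    lp += float(np.sum(norm.logpdf(obs_params.p_alive[p_mask], 0.0, sd_n)))
    return ll + lp


# --------------------------------------------------------------------------
# chain drivers
# --------------------------------------------------------------------------

def _init_state(data: SurveyDataset, X: np.ndarray, rng: np.random.Generator, cfg: McmcConfig):
    """Crude saturated starting values.

    a_ij starts at the dead-status crude rate log((N_ij1 + 0.5) / (S_j V_j));
    e_j2 at log V_j plus the log alive/dead count ratio of the unit (pooled
    over species), so the alive-effort random walk starts near the data
    rather than at 0; p_i2 at 0.  gamma ~ Bernoulli(0.5), beta = 0, a0 = the
    mean of the focal starting row, tau = 1.
    """
    I, J, R = data.I, data.J, X.shape[1]
    a = np.log((data.counts[:, :, 0] + 0.5) / (data.surface * data.km)[None, :])
    alive = data.counts[:, :, 1].sum(axis=0)
    dead = data.counts[:, :, 0].sum(axis=0)
    e2 = np.log(data.km) + np.log((alive + 0.5) / (dead + 0.5))
    p2 = np.zeros(I)
    if cfg.frozen_gamma is not None:
        if cfg.frozen_gamma.shape != (R,):
            raise BadDimension("frozen_gamma must have one entry per covariate")
        gamma = cfg.frozen_gamma.copy()
    else:
        gamma = (rng.random(R) < GAMMA_PRIOR_PROB).astype(np.int64)
    beta = np.zeros(R)
    a0 = float(a[data.focal].mean())
    tau = 1.0 if cfg.fix_tau is None else float(cfg.fix_tau)
    return a, e2, p2, gamma, beta, a0, tau


def _run_chain(data: SurveyDataset, Xm: np.ndarray, cfg: McmcConfig, chain: int):
    seed = cfg.seed + chain
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    _seed_kernel(seed % (2**32))
    I, J, R = data.I, data.J, Xm.shape[1]
    a, e2, p2, gamma, beta, a0, tau = _init_state(data, Xm, rng, cfg)

    counts = np.ascontiguousarray(data.counts, dtype=np.int64)
    nsum = counts.sum(axis=2).astype(np.float64)
    nal_j = counts[:, :, 1].sum(axis=0).astype(np.float64)
    nal_i = counts[:, :, 1].sum(axis=1).astype(np.float64)
    log_s = np.log(data.surface)
    log_v = np.log(data.km)
    sxx = (Xm * Xm).sum(axis=0)
    gamma_logit = float(np.log(GAMMA_PRIOR_PROB) - np.log1p(-GAMMA_PRIOR_PROB))

    params = ObservationParams(a=a, e_alive=e2, p_alive=p2)
    lam = np.exp(compute_log_intensity(params, data))
    mu = a0 + Xm @ (gamma * beta)

    scale_a = np.full((I, J), cfg.proposal_sd_a)
    scale_e = np.full(J, cfg.proposal_sd_e)
    scale_p = np.full(I, cfg.proposal_sd_p)
    acc_a = np.zeros((I, J), dtype=np.int64)
    acc_e = np.zeros(J, dtype=np.int64)
    acc_p = np.zeros(I, dtype=np.int64)

    n_keep = cfg.n_keep
    keep = {
        "gamma": np.empty((n_keep, R), dtype=np.int64),
        "beta": np.empty((n_keep, R)),
        "a0": np.empty(n_keep),
        "tau": np.empty(n_keep),
        "a_b": np.empty((n_keep, J)),
        "e_alive": np.empty((n_keep, J)),
        "p_alive": np.empty((n_keep, I)),
    }
    lo, hi = TAU_SUPPORT
    update_gamma = cfg.frozen_gamma is None
    total = cfg.n_burn + cfg.n_iter
    k = 0
    since_adapt = 0
    for it in range(1, total + 1):
        a0, ssr = _sweep(
            counts, nsum, nal_j, nal_i, log_s, log_v,
            a, e2, p2, lam, Xm, gamma, beta, a0, tau, mu,
            data.focal, 0, sxx, True, update_gamma,
            scale_a, scale_e, scale_p, acc_a, acc_e, acc_p,
            NUISANCE_PRIOR_PRECISION, BETA_PRIOR_PRECISION, A0_PRIOR_PRECISION,
            gamma_logit,
        )
        if cfg.fix_tau is None:
            tau = _truncated_gamma_icdf(J / 2.0 + 1.0, ssr / 2.0, lo, hi, float(rng.uniform()))
        since_adapt += 1
        if it <= cfg.n_burn:
            if cfg.adapt and since_adapt == cfg.adapt_window:
                for scale, acc in ((scale_a, acc_a), (scale_e, acc_e), (scale_p, acc_p)):
                    rate = acc / cfg.adapt_window
                    np.multiply(scale, np.exp(0.6 * (rate - cfg.adapt_target)), out=scale)
                    np.clip(scale, 1e-3, 10.0, out=scale)
                    acc[:] = 0
                since_adapt = 0
            if it == cfg.n_burn:
                acc_a[:] = 0
                acc_e[:] = 0
                acc_p[:] = 0
        elif (it - cfg.n_burn) % cfg.thin == 0:
            if not (np.isfinite(a0) and np.isfinite(ssr)):
                raise NonFiniteState(f"chain {chain} diverged at sweep {it}")
            keep["gamma"][k] = gamma
            keep["beta"][k] = beta
            keep["a0"][k] = a0
            keep["tau"][k] = tau
            keep["a_b"][k] = a[data.focal]
            keep["e_alive"][k] = e2
            keep["p_alive"][k] = p2
            k += 1
    if not np.all(np.isfinite(keep["a_b"])):
        raise NonFiniteState(f"chain {chain} produced non-finite abundance draws")
    denom = cfg.n_iter
    acceptance = {
        "a": acc_a / denom,
        "e_alive": acc_e / denom,
        "p_alive": np.delete(acc_p, 0) / denom,
    }
    return keep, acceptance


def _run_regression_chain(a_b: np.ndarray, Xm: np.ndarray, cfg: McmcConfig, chain: int):
    """Selection level only, with a_b supplied as data (no observation level)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + chain))
    J, R = Xm.shape
    if cfg.frozen_gamma is not None:
        gamma = cfg.frozen_gamma.copy()
    else:
        gamma = (rng.random(R) < GAMMA_PRIOR_PROB).astype(np.int64)
    state = SelectionState(
        gamma=gamma,
        beta=np.zeros(R),
        a0=float(a_b.mean()),
        tau=1.0 if cfg.fix_tau is None else float(cfg.fix_tau),
    )
    n_keep = cfg.n_keep
    keep = {
        "gamma": np.empty((n_keep, R), dtype=np.int64),
        "beta": np.empty((n_keep, R)),
        "a0": np.empty(n_keep),
        "tau": np.empty(n_keep),
        "a_b": np.empty((n_keep, J)),
        "e_alive": np.empty((n_keep, 0)),
        "p_alive": np.empty((n_keep, 0)),
    }
    update_gamma = cfg.frozen_gamma is None
    k = 0
    for it in range(1, cfg.n_burn + cfg.n_iter + 1):
        state.a0 = draw_a0_conditional(state, a_b, Xm, rng)
        for r in range(R):
            if update_gamma:
                p1 = gamma_full_conditional(r, state, a_b, Xm)
                state.gamma[r] = 1 if rng.uniform() < p1 else 0
            state.beta[r] = draw_beta_conditional(r, state, a_b, Xm, rng)
        if cfg.fix_tau is None:
            state.tau = draw_tau_conditional(state, a_b, Xm, rng)
        if it > cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            keep["gamma"][k] = state.gamma
            keep["beta"][k] = state.beta
            keep["a0"][k] = state.a0
            keep["tau"][k] = state.tau
            keep["a_b"][k] = a_b
            k += 1
    return keep, {}


def run_mcmc(
    data: SurveyDataset | None,
    X,
    config: McmcConfig,
    a_b_fixed: np.ndarray | None = None,
) -> PosteriorDraws:
    """Sample the joint posterior of both model levels.

    With ``a_b_fixed`` given, the observation level is disabled and the
    regression level is fitted to the supplied focal log-abundances
    directly (a Gaussian-likelihood run, used by the exact-enumeration
    cross-checks).  Otherwise ``data`` and ``X`` must describe the same
    units; units with zero kilometres are dropped with a warning before
    fitting.  Deterministic given ``config.seed``.
    """
    cov_names = list(X.columns) if isinstance(X, CovariateMatrix) else [
        f"x{r + 1}" for r in range(np.asarray(X).shape[1])
    ]
    Xm = np.ascontiguousarray(X.X if isinstance(X, CovariateMatrix) else X, dtype=float)

    if a_b_fixed is not None:
        a_b_fixed = np.asarray(a_b_fixed, dtype=float)
        if a_b_fixed.shape != (Xm.shape[0],):
            raise BadDimension("a_b_fixed must have one entry per unit")
        unit_ids = (
            X.unit_ids if isinstance(X, CovariateMatrix)
            else np.arange(Xm.shape[0])
        )
        runner = lambda c: _run_regression_chain(a_b_fixed, Xm, config, c)  # noqa: E731
    else:
        if data is None:
            raise BadDimension("either data or a_b_fixed must be provided")
        if config.focal_species is not None and config.focal_species != data.focal:
            data = replace(data, focal=config.focal_species)
        if isinstance(X, CovariateMatrix) and not np.array_equal(
            np.asarray(X.unit_ids), np.asarray(data.unit_ids)
        ):
            raise UnitMismatch("covariate matrix and survey data disagree on unit ids")
        if data.zero_effort_units.any():
            n_zero = int(data.zero_effort_units.sum())
            logger.warning("dropping %d unit(s) with zero kilometres travelled", n_zero)
            keep_mask = ~data.zero_effort_units
            data = data.drop_zero_effort()
            Xm = Xm[keep_mask]
        if Xm.shape[0] != data.J:
            raise BadDimension("covariate matrix and survey data disagree on J")
        unit_ids = data.unit_ids
        runner = lambda c: _run_chain(data, Xm, config, c)  # noqa: E731

    chains = [runner(c) for c in range(config.n_chains)]
    stack = {
        key: np.stack([kept[key] for kept, _ in chains])
        for key in chains[0][0]
    }
    iterations = np.arange(1, config.n_keep + 1) * config.thin
    return PosteriorDraws(
        gamma=stack["gamma"],
        beta=stack["beta"],
        a0=stack["a0"],
        tau=stack["tau"],
        a_b=stack["a_b"],
        e_alive=stack["e_alive"],
        p_alive=stack["p_alive"],
        iterations=iterations,
        covariate_names=cov_names,
        unit_ids=np.asarray(unit_ids),
        acceptance={c: acc for c, (_, acc) in enumerate(chains)},
        config=config,
    )


# --------------------------------------------------------------------------
# cross-chain mixing diagnostic
# --------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Cross-chain agreement of the posterior inclusion probabilities.

    ``max_diff[r]`` is the largest absolute difference of p_r across
    chains; the run passes when every difference is below ``tolerance``.
    """

    covariate_names: list[str]
    per_chain: np.ndarray         # (C, R) per-chain p_r
    max_diff: np.ndarray          # (R,)
    tolerance: float
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        worst = self.covariate_names[int(np.argmax(self.max_diff))]
        return (
            f"cross-chain agreement {status}: max |Δp_r| = "
            f"{self.max_diff.max():.4f} ({worst}), tolerance {self.tolerance}"
        )


def check_chain_agreement(draws: PosteriorDraws, tolerance: float = 0.05) -> AgreementReport:
    """Compare per-chain inclusion probabilities, the mixing check.

    The chains are judged to have mixed when the posterior probability of
    every indicator gamma_r agrees across chains to within ``tolerance``.
    """
    if draws.n_chains < 2:
        raise SingleChain("the agreement check needs at least two chains")
    per_chain = draws.gamma.mean(axis=1)          # (C, R)
    max_diff = per_chain.max(axis=0) - per_chain.min(axis=0)
    return AgreementReport(
        covariate_names=list(draws.covariate_names),
        per_chain=per_chain,
        max_diff=max_diff,
        tolerance=tolerance,
        passed=bool(np.all(max_diff < tolerance)),
    )
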