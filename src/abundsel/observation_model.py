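"""Poisson observation level of the hierarchical abundance model.

A roadside registry records, for each of I species and J spatial units, the
number of animals detected dead (status k=1) and alive (k=2).  The count
N_ijk is modelled as Poisson with intensity

    lambda_ijk = S_j * A_ij * E_jk * P_ik,

where S_j is the unit's surface area, A_ij the true density of species i,
E_jk the sampling effort in unit j for status k, and P_ik the detection
probability of species i in status k.  These natural parameters are not
jointly identifiable; the model is fitted in the equivalent log-linear form

    log lambda_ijk = s_j + a_ij + e_jk + p_ik

with s_j = log S_j fixed, the dead-status effort anchored to the kilometres
driven (e_j1 = log V_j), and the detectability offsets constrained to
p_i1 = 0 for every species and p_1k = 0 for the reference species.  Under
these constraints every free parameter is identifiable and a_ij is the
log-*relative* abundance of species i: true density times an unknown
species-specific constant.  The proportionality constant between kilometres
and dead-status effort is absorbed into a_ij, which is harmless precisely
because a_ij is only defined up to a constant.

The alive-status effort e_j2 is a free parameter per unit, identified by
pooling all species: every species surveyed shares the same alive effort,
which is the point of fitting the model to the whole multi-species registry
rather than to the focal species alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import BadDimension, NonPositiveParam, ZeroEffortUnit

__all__ = [
    "SurveyDataset",
    "NaturalParams",
    "ObservationParams",
    "compute_log_intensity",
    "survey_log_likelihood",
    "natural_to_reduced",
]

#: status axis order used throughout: index 0 = dead (k=1), 1 = alive (k=2)
STATUS_LABELS = ("dead", "alive")


@dataclass
class SurveyDataset:
    """Complete I x J x 2 count array with per-unit surface and effort.

    ``counts[i, j, k]`` is the number of species-i animals recorded in unit
    j with status k (0 = dead, 1 = alive).  ``surface`` is S_j in km^2 and
    ``km`` is V_j, the kilometres travelled in unit j.  Species index 0 is
    the reference species of the identifiability constraints; ``focal`` is
    the index of the species receiving the regression level.
    """

    counts: np.ndarray            # (I, J, 2) nonnegative ints
    surface: np.ndarray           # (J,) km^2, > 0
    km: np.ndarray                # (J,) km travelled, >= 0
    species: list[str]
    unit_ids: np.ndarray
    focal: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.surface = np.asarray(self.surface, dtype=float)
        self.km = np.asarray(self.km, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        I, J = len(self.species), len(self.unit_ids)
        if self.counts.shape != (I, J, 2):
            raise BadDimension(
                f"counts must be (I={I}, J={J}, 2); got {self.counts.shape}"
            )
        if self.surface.shape != (J,) or self.km.shape != (J,):
            raise BadDimension("surface and km must have one entry per unit")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.surface <= 0):
            raise NonPositiveParam("surface areas S_j must be strictly positive")
        if np.any(self.km < 0):
            raise NonPositiveParam("kilometres V_j cannot be negative")
        if not 0 <= self.focal < I:
            raise BadDimension(f"focal species index {self.focal} out of range")

    @property
    def I(self) -> int:
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def zero_effort_units(self) -> np.ndarray:
        """Boolean mask of units with V_j = 0 (must be dropped before fitting)."""
        return self.km == 0

    def drop_zero_effort(self) -> "SurveyDataset":
        """Return a copy without the V_j = 0 units (no-op if none)."""
        keep = ~self.zero_effort_units
        if keep.all():
            return self
        return SurveyDataset(
            counts=self.counts[:, keep, :],
            surface=self.surface[keep],
            km=self.km[keep],
            species=list(self.species),
            unit_ids=self.unit_ids[keep],
            focal=self.focal,
        )


@dataclass
class NaturalParams:
    """Natural-scale intensity factors (density, effort, detectability).

    Not identifiable from counts; exists to express the equivalence with the
    reduced log-linear parametrization and to seed simulations.
    """

    A: np.ndarray                 # (I, J) true density > 0
    E: np.ndarray                 # (J, 2) effort > 0
    P: np.ndarray                 # (I, 2) detection probability in (0, 1]
    beta_const: float = 1.0       # proportionality constant beta > 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.A <= 0) or np.any(self.E <= 0) or self.beta_const <= 0:
            raise NonPositiveParam("A, E and beta_const must be strictly positive")
        if np.any(self.P <= 0) or np.any(self.P > 1):
            raise NonPositiveParam("detection probabilities must lie in (0, 1]")

    def log_intensity(self, data: SurveyDataset) -> np.ndarray:
        """log(S_j A_ij E_jk P_ik), the natural-scale factorization."""
        return (
            np.log(data.surface)[None, :, None]
            + np.log(self.A)[:, :, None]
            + np.log(self.E)[None, :, :]
            + np.log(self.P)[:, None, :]
        )


@dataclass
class ObservationParams:
    """Identifiable log-scale parameters of the observation level.

    Free parameters: ``a`` (I x J log-relative abundances), ``e_alive``
    (length-J alive-status log effort) and ``p_alive`` (length-I alive
    detectability offsets, reference entry fixed at 0).  The dead-status
    offsets are not free: e_j1 = log V_j and p_i1 = 0 by construction.
    """

    a: np.ndarray                 # (I, J)
    e_alive: np.ndarray           # (J,)
    p_alive: np.ndarray           # (I,), p_alive[reference] == 0
    reference: int = 0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.e_alive = np.asarray(self.e_alive, dtype=float)
        self.p_alive = np.asarray(self.p_alive, dtype=float)
        I, J = self.a.shape
        if self.e_alive.shape != (J,) or self.p_alive.shape != (I,):
            raise BadDimension("e_alive must be length J and p_alive length I")
        if not (
            np.all(np.isfinite(self.a))
            and np.all(np.isfinite(self.e_alive))
            and np.all(np.isfinite(self.p_alive))
        ):
            raise ValueError("observation parameters must be finite")
        if self.p_alive[self.reference] != 0.0:
            raise ValueError("p_alive must be exactly 0 for the reference species")


def _check_effort(data: SurveyDataset) -> None:
    if np.any(data.km == 0):
        raise ZeroEffortUnit(
            "units with V_j = 0 present; call SurveyDataset.drop_zero_effort() first"
        )


def compute_log_intensity(params: ObservationParams, data: SurveyDataset) -> np.ndarray:
    """log lambda_ijk = s_j + a_ij + e_jk + p_ik as an (I, J, 2) array.

    Fixed offsets: s_j = log S_j, e_j1 = log V_j, p_i1 = 0.
    """
    _check_effort(data)
    I, J = params.a.shape
    if (I, J) != (data.I, data.J):
        raise BadDimension("parameter dimensions do not match the dataset")
    e = np.stack([np.log(data.km), params.e_alive], axis=1)          # (J, 2)
    p = np.stack([np.zeros(I), params.p_alive], axis=1)              # (I, 2)
    return (
        np.log(data.surface)[None, :, None]
        + params.a[:, :, None]
        + e[None, :, :]
        + p[:, None, :]
    )


def survey_log_likelihood(params: ObservationParams, data: SurveyDataset) -> float:
    """Poisson log likelihood sum_ijk [N log(lambda) - lambda - log(N!)]."""
    log_lam = compute_log_intensity(params, data)
    N = data.counts
    return float(np.sum(N * log_lam - np.exp(log_lam) - gammaln(N + 1.0)))


def natural_to_reduced(nat: NaturalParams, data: SurveyDataset) -> ObservationParams:
    """Map natural parameters to the identifiable log-linear parametrization.

    With beta the dead-effort proportionality constant, the reduced
    parameters are

        a_ij = log beta + log P_i1 + log A_ij
        e_jk = log(E_jk / beta) + log(P_1k / P_11)
        p_ik = log(P_ik / P_1k) + log(P_11 / P_i1)

    which by construction give p_i1 = 0 for every species and p_1k = 0 for
    the reference species, and leave every lambda_ijk unchanged.  The
    returned e_alive is taken relative to log V_j so that the package's
    e_j1 = log V_j anchoring reproduces the same intensities when
    E_j1 = beta * V_j.
    """
    b = nat.beta_const
    logA, logE, logP = np.log(nat.A), np.log(nat.E), np.log(nat.P)
    a = np.log(b) + logP[:, 0][:, None] + logA                       # (I, J)
    e = logE - np.log(b) + (logP[0, :] - logP[0, 0])[None, :]        # (J, 2)
    p = logP - logP[0, :][None, :] + (logP[0, 0] - logP[:, 0])[:, None]
    # absorb the offset between e_j1 and the package anchoring log V_j into a
    shift = e[:, 0] - np.log(data.km)
    a = a + shift[None, :]
    e = e - shift[:, None]
    p[:, 0] = 0.0                                                    # exact zeros
    p[0, :] = 0.0
    return ObservationParams(a=a, e_alive=e[:, 1], p_alive=p[:, 1])
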