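"""Preparation of per-unit environmental covariates.

Raw environmental tables arrive as one row per spatial unit (a small
agricultural region, SAR) with named real-valued columns: landscape metrics,
soil indices, food-resource proxies, 24 monthly climate columns and mean
elevation.  The regression level of the model consumes a standardized design
matrix, so this module provides

* column standardization to mean 0 / sd 1 (sample sd, denominator J-1),
* a principal-component reduction of the 24 monthly climate columns
  (correlation-matrix PCA, first components retained as synthetic climate
  axes), and
* a split of units into lowland and mountain strata at an elevation
  threshold, so each stratum can be modelled separately.

Tables are plain :class:`pandas.DataFrame` objects with a ``unit_id`` column;
the standardized output is the :class:`CovariateMatrix` container used by the
rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstantColumn, MissingColumn, MissingValue

__all__ = [
    "CLIMATE_COLUMNS",
    "CovariateMatrix",
    "standardize_columns",
    "climate_pca",
    "split_by_elevation",
    "read_covariate_table",
]

#: Canonical names of the 24 monthly climate columns: average monthly
#: temperature (degC) and rainfall (mm).
CLIMATE_COLUMNS: tuple[str, ...] = tuple(
    f"temp_{m:02d}" for m in range(1, 13)
) + tuple(f"rain_{m:02d}" for m in range(1, 13))


@dataclass
class CovariateMatrix:
    """Standardized J x R design matrix with row and column labels.

    Every column has mean 0 and standard deviation 1 over the J units
    (except when the matrix holds raw PCA scores, where columns are merely
    centred; standardize again before regression if needed).
    """

    unit_ids: np.ndarray          # length J, unit identifiers
    X: np.ndarray                 # (J, R) float matrix
    columns: list[str]            # length R labels
    explained_variance: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.unit_ids):
            raise ValueError("X must be (J, R) with one row per unit id")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column labels must match the number of columns")

    @property
    def J(self) -> int:
        return self.X.shape[0]

    @property
    def R(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.X, columns=self.columns)
        out.insert(0, "unit_id", self.unit_ids)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CovariateMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "unit_id":
            raise MissingColumn("first column of a covariate CSV must be unit_id")
        return cls(
            unit_ids=df["unit_id"].to_numpy(),
            X=df.iloc[:, 1:].to_numpy(dtype=float),
            columns=list(df.columns[1:]),
        )


def read_covariate_table(path) -> pd.DataFrame:
    """Read a raw covariate CSV (header row, ``unit_id`` first column)."""
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise MissingColumn("raw covariate table must contain a unit_id column")
    if df["unit_id"].duplicated().any():
        raise MissingValue("duplicate unit_id rows in covariate table")
    return df


def _require_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise MissingColumn(f"columns not found in table: {missing}")
    bad = [c for c in columns if table[c].isna().any()]
    if bad:
        raise MissingValue(f"missing values in columns: {bad}")


def standardize_columns(table: pd.DataFrame, columns: list[str]) -> CovariateMatrix:
    """Centre and scale the named columns to mean 0, sd 1.

    The sample standard deviation (denominator J-1) is used.  Unit order is
    preserved.  Raises :class:`ConstantColumn` for a zero-variance column.
    """
    _require_columns(table, ["unit_id", *columns])
    raw = table[list(columns)].to_numpy(dtype=float)
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        offenders = [c for c, s in zip(columns, sd) if not (np.isfinite(s) and s > 0)]
        raise ConstantColumn(f"zero-variance columns cannot be standardized: {offenders}")
    X = (raw - raw.mean(axis=0)) / sd
    return CovariateMatrix(
        unit_ids=table["unit_id"].to_numpy(), X=X, columns=list(columns)
    )


def climate_pca(
    table: pd.DataFrame,
    n_components: int = 3,
    columns: tuple[str, ...] = CLIMATE_COLUMNS,
) -> CovariateMatrix:
    """Principal components of the monthly climate columns.

    The PCA is run on the correlation matrix (each column centred and scaled
    before the eigendecomposition), so temperature and rainfall enter on a
    common footing despite their different units.  Unit scores on the first
    ``n_components`` axes are returned; ``explained_variance`` on the result
    holds the eigenvalue fractions for those axes.

    Sign convention: each retained axis is flipped, if necessary, so that the
    largest-magnitude loading on it is positive.  This makes component signs
    reproducible across linear-algebra backends.
    """
    if n_components < 1 or n_components > len(columns):
        raise ValueError("n_components must be between 1 and the number of climate columns")
    _require_columns(table, ["unit_id", *columns])
    Z = standardize_columns(table, list(columns)).X
    J = Z.shape[0]
    corr = (Z.T @ Z) / (J - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # fix each loading vector's sign by its largest-magnitude entry
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    frac = eigval / eigval.sum()
    scores = Z @ eigvec[:, :n_components]
    return CovariateMatrix(
        unit_ids=table["unit_id"].to_numpy(),
        X=scores,
        columns=[f"climate_pc{k + 1}" for k in range(n_components)],
        explained_variance=frac[:n_components],
    )


def split_by_elevation(
    table: pd.DataFrame, threshold_m: float = 400.0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition unit ids into (lowland, mountain) at an elevation threshold.

    Units with mean elevation strictly below ``threshold_m`` are lowland;
    units at or above it are mountain (the boundary goes to the mountain
    group).  Requires a ``mean_elevation`` column with no missing values.
    """
    _require_columns(table, ["unit_id", "mean_elevation"])
    elev = table["mean_elevation"].to_numpy(dtype=float)
    ids = table["unit_id"].to_numpy()
    low = elev < threshold_m
    return ids[low], ids[~low]
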