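"""Exception hierarchy shared across the package.

Every error raised on bad user input or a degenerate numerical state derives
from :class:`AbundselError`, so callers can catch the package's failures with
a single except clause while still distinguishing the specific condition.
"""


class AbundselError(Exception):
    """Base class for all errors raised by abundsel."""


# --- covariate preparation -------------------------------------------------

class MissingColumn(AbundselError):
    """A named column is absent from the input table."""


class MissingValue(AbundselError):
    """A column used downstream contains missing (NaN) entries."""


class ConstantColumn(AbundselError):
    """A column has zero variance and cannot be standardized."""


# --- model structure -------------------------------------------------------

class BadDimension(AbundselError):
    """Array shapes or lengths do not agree with the declared dimensions."""


class BadIndex(AbundselError):
    """A covariate or species index is out of range."""


class NonPositiveParam(AbundselError):
    """A natural-scale parameter that must be strictly positive is not."""


class ZeroEffortUnit(AbundselError):
    """A spatial unit with zero kilometres travelled was not dropped."""


# --- sampling and summaries ------------------------------------------------

class NonFiniteState(AbundselError):
    """The sampler reached a non-finite parameter state (divergence)."""


class SingleChain(AbundselError):
    """A cross-chain diagnostic was requested with fewer than two chains."""


class EmptyDraws(AbundselError):
    """A posterior summary was requested on an empty set of draws."""


class DegenerateRange(AbundselError):
    """All posterior means equal; the [0, 1] index rescale is undefined."""


# --- file input ------------------------------------------------------------

class SchemaError(AbundselError):
    """An input CSV does not match the expected column schema."""


class UnknownStatus(AbundselError):
    """A detection record carries a status other than 'dead' or 'alive'."""


class DuplicateRecord(AbundselError):
    """The same species/unit/status combination appears more than once."""


class UnitMismatch(AbundselError):
    """Counts reference spatial units absent from the effort table."""
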