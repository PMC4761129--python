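"""Exception hierarchy.

``ParameterError`` subclasses :class:`ValueError` so sklearn-style parameter
validation behaves as callers expect; ``DataError`` covers malformed or
insufficient input series.
"""


class GaitSPCError(Exception):
    """Base class for all package errors."""


class ParameterError(GaitSPCError, ValueError):
    """An estimator/model parameter is outside its admissible range."""


class DomainError(GaitSPCError, ValueError):
    """An input value is outside the mathematical domain (e.g. x <= 0)."""


class DataError(GaitSPCError):
    """Input data are malformed or insufficient."""


class InitializationError(DataError):
    """The initialization window does not contain enough usable days."""


class StandardizationError(DataError):
    """Baseline sigma is zero; standardized observations are undefined."""


class FitError(GaitSPCError):
    """Maximum-likelihood fitting failed to converge."""


class CatalogError(GaitSPCError, KeyError):
    """Unknown scenario identifier."""


class SpecificationError(GaitSPCError, ValueError):
    """Ground-truth windows are inconsistent (overlapping or unordered)."""
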