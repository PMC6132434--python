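"""Exception hierarchy.

``ConfigurationError`` and ``InputError`` map to CLI exit code 1 (user-fixable);
everything else is an internal error (exit code 2).
"""


class IsosubError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IsosubError, ValueError):
    """A parameter or config file value is out of its documented range."""


class InputError(IsosubError, ValueError):
    """Input data violates a documented contract (bad counts, bad ages, ...)."""


class StructuralError(InputError):
    """An epoch stream has gaps or misaligned timestamps."""


class RankDeficiencyError(IsosubError, ValueError):
    """A design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"design matrix is rank deficient; offending columns: {self.columns}")


class DegenerateFitError(IsosubError, ValueError):
    """A model cannot be estimated (constant outcome, empty stratum, ...)."""


class EstimationError(IsosubError, RuntimeError):
    """Estimation failed for a structural reason (too few clusters, ...)."""
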