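"""Exception hierarchy shared across the package."""


class Sift2dError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Sift2dError):
    """A file does not conform to its declared format (MRC/STAR/CSV)."""


class SchemaError(Sift2dError):
    """A table is missing a required column or has an unparsable cell."""


class ValidationError(Sift2dError):
    """An input value violates a documented precondition or invariant."""


class InsufficientDataError(ValidationError):
    """Too few records/points for the requested operation."""


class ConfigurationError(Sift2dError):
    """Model manifest or run configuration is incomplete or inconsistent."""


class ConsistencyError(Sift2dError):
    """Backend or state bookkeeping violated a structural contract."""
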