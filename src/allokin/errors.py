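"""Exception hierarchy shared across the package."""


class AllokinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AllokinError):
    """A file does not conform to the expected dialect (missing columns, ...)."""


class IntegrityError(AllokinError):
    """Input violates a uniqueness or consistency invariant."""


class LookupStateError(AllokinError, KeyError):
    """A requested state label is not present in the table."""


class InsufficientDataError(AllokinError):
    """Too few residues/states/points to perform the requested analysis."""


class DomainError(AllokinError, ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""


class ConfigError(AllokinError):
    """Invalid or incomplete configuration."""


class FitError(AllokinError):
    """A non-linear fit failed to converge or returned unphysical estimates."""
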