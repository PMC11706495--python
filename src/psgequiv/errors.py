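"""Exception hierarchy shared across the package."""


class PsgEquivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PsgEquivError):
    """A file does not conform to its declared format (names the offending field)."""


class UnsupportedDialectError(FormatError):
    """A format variant we deliberately do not read (e.g. discontinuous EDF+)."""


class ValidationError(PsgEquivError, ValueError):
    """Well-formed input whose content violates a domain invariant."""


class InsufficientDataError(PsgEquivError):
    """Too few observations to run a statistical procedure."""


class DegenerateInputError(PsgEquivError):
    """Zero-variance or otherwise degenerate input to a statistic."""
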