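"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError/ValidationError -> 2,
DataError (incl. subject exclusion) -> 3, ScreeningError -> 4.
"""


class RestEEGError(Exception):
    """Base class for all package errors."""


class ValidationError(RestEEGError):
    """Invalid in-memory object (shape mismatch, NaN samples, bad field)."""


class ConfigError(RestEEGError):
    """Invalid analysis parameters (bands, rates, windows, unknown keys)."""


class FormatError(RestEEGError):
    """Unreadable or malformed file content."""


class ChannelError(FormatError):
    """A required channel is missing from a recording file."""


class ParseError(FormatError):
    """Malformed metadata or feature-table text."""


class DataError(RestEEGError):
    """Data does not support the requested computation (too short, empty)."""


class SubjectExclusionError(DataError):
    """Too few clean epochs survive rejection for this subject/condition."""


class DegenerateSpectrumError(DataError):
    """All-zero or otherwise degenerate power spectrum."""


class ScreeningError(RestEEGError):
    """Feature screening left no features."""
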