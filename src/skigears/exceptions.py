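"""Exception hierarchy for skigears.

All package errors derive from :class:`SkigearsError` so callers (and the
command-line interface) can distinguish domain errors from programming
errors.
"""


class SkigearsError(Exception):
    """Base class for all skigears errors."""


class FormatError(SkigearsError):
    """A file does not have the expected structure (columns, header)."""


class ValidationError(SkigearsError):
    """Data violates a domain invariant (monotonic time, overlap, shape)."""


class VocabularyError(ValidationError):
    """A gear label outside the five-gear vocabulary was encountered."""


class InsufficientDataError(SkigearsError):
    """Too few observations to estimate the requested quantity."""


class CoverageError(SkigearsError):
    """Training data does not cover every gear class."""


class ModelIntegrityError(SkigearsError):
    """A stored model violates its own invariants (e.g. non-PD covariance)."""


class DegenerateInputError(SkigearsError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class ConfigError(SkigearsError):
    """A configuration file or mapping is invalid (unknown keys, bad values)."""
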