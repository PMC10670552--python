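"""Exception hierarchy shared across the toolkit.

All toolkit errors derive from :class:`EcgQualError` so callers (and the CLI)
can distinguish configuration, data, and format problems and map them onto
exit codes.
"""


class EcgQualError(Exception):
    """Base class for every error raised by ecgqual."""


class InvalidArgumentError(EcgQualError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigError(EcgQualError):
    """A configuration file or config object fails validation."""


class DataError(EcgQualError):
    """Input data is structurally valid but unusable (shape/label mismatch,
    empty corpus, unachievable class ratio, ...)."""


class FormatError(EcgQualError):
    """A waveform or manifest file cannot be parsed."""


class MissingRateError(FormatError):
    """A text waveform was given with no sampling rate hint or configured
    default."""


class SplitError(DataError):
    """A requested corpus split cannot be realized (e.g. one group larger
    than the training partition in group-aware mode)."""


class ShapeError(DataError):
    """An array does not have the shape a stage expects; the message names
    expected vs actual."""


class ModelStoreError(EcgQualError):
    """A model archive is corrupt, truncated, or has an unsupported
    version."""
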