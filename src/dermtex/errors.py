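"""Exception hierarchy.

Every stage raises a subclass of :class:`DermtexError` so callers can
distinguish pipeline failures from programming errors.
"""


class DermtexError(Exception):
    """Base class for all package errors."""


class InputError(DermtexError):
    """Missing or malformed input (file not found, empty data, ...)."""


class FormatError(DermtexError):
    """A file exists but cannot be decoded in the expected format."""


class SizeError(DermtexError):
    """An image or plane is too small for the requested operation."""


class ConfigError(DermtexError):
    """An unknown identifier or an inconsistent configuration."""


class ShapeError(DermtexError):
    """Array dimensions do not match between related inputs."""


class UsageError(DermtexError):
    """An operation was called with arguments outside its contract."""


class BalanceError(DermtexError):
    """Oversampling cannot proceed (e.g. a class with a single member)."""


class TrainingError(DermtexError):
    """The training set is degenerate (e.g. a single class)."""


class SplitError(DermtexError):
    """A train/test split left a class empty."""


class ComparisonError(DermtexError):
    """Two run reports are not comparable (different test sets)."""
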