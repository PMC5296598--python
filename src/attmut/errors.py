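"""Exception hierarchy shared across the package.

Every error raised by attmut derives from :class:`AttmutError` so callers can
catch package failures with a single except clause; the subclasses map onto
distinct CLI exit codes.
"""


class AttmutError(Exception):
    """Base class for all attmut errors."""

    exit_code = 1


class ParameterError(AttmutError, ValueError):
    """A function argument is outside its documented domain."""

    exit_code = 2


class InputError(AttmutError):
    """An input file or record is malformed or inconsistent."""

    exit_code = 3


class GenerationError(AttmutError):
    """The synthetic-data generator cannot satisfy the request."""

    exit_code = 4


class ModelError(AttmutError):
    """A locus or model object violates its structural invariants."""

    exit_code = 5


class FitError(AttmutError):
    """A statistical fit is degenerate or underdetermined."""

    exit_code = 6


class ConfigurationError(AttmutError):
    """An assay or pipeline configuration fails its own self-check."""

    exit_code = 7
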