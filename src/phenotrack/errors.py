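"""Exception hierarchy. Exit codes used by the CLI live on the classes."""


class PhenotrackError(Exception):
    """Base class for all package errors."""

    exit_code = 4  # processing failure


class ConfigError(PhenotrackError):
    """Invalid configuration or parameter combination."""

    exit_code = 2


class InputError(PhenotrackError):
    """Missing or unreadable input."""

    exit_code = 3


class FormatError(InputError):
    """Input exists but its structure is inconsistent."""


class SegmentationError(PhenotrackError):
    """No usable assembloid found in a frame."""


class RegistrationError(PhenotrackError):
    """Template/region matching could not produce an estimate."""


class MetricError(PhenotrackError):
    """A metric is undefined for the given trajectory."""
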