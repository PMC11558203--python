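"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RamanScreenError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class RamanScreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RamanScreenError):
    """A file did not parse as the declared format."""


class GridMismatchError(RamanScreenError):
    """Spectra do not share a common wavenumber grid."""


class ConfigError(RamanScreenError):
    """A configuration value is missing, unknown, or out of range."""


class ParameterError(RamanScreenError):
    """An operation received an out-of-contract parameter."""


class DespikeError(RamanScreenError):
    """Cosmic-ray removal refused a trace (too many flagged channels)."""


class ZeroVarianceError(RamanScreenError):
    """A constant trace or vector where variation is required."""


class StageError(RamanScreenError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
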