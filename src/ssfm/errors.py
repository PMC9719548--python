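"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, validation-type errors
(ValidationError, CoverageError, GridMismatchError, EmptySignalError,
PipelineError) -> 3, I/O (OSError, FormatError) -> 4.
"""


class SSFMError(Exception):
    """Base class for all package errors."""


class FormatError(SSFMError):
    """A cube or config file does not conform to a documented dialect."""


class GridMismatchError(SSFMError):
    """Per-pixel wavelength vectors disagree with the shared grid."""


class ValidationError(SSFMError):
    """Data fails an invariant (negative intensities, bad grid, ...)."""


class CoverageError(SSFMError):
    """Wavelength grid does not cover a required spectral region."""


class EmptySignalError(SSFMError):
    """A spectrum carries no usable signal in the emission band."""


class RangeError(SSFMError):
    """A value falls outside the calibration span."""


class PipelineError(SSFMError):
    """Too many pixels failed a pipeline stage."""


class ConfigError(SSFMError):
    """Invalid pipeline configuration or phantom specification."""


class UnsupportedOperationError(SSFMError):
    """A documented-but-unimplemented mode was requested."""
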