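"""Exception and warning hierarchy for eprshape."""


class EPRShapeError(Exception):
    """Base class for all eprshape errors."""


class SpectrumFormatError(EPRShapeError):
    """A spectrum file or in-memory spectrum violates the expected format."""


class BaselineError(EPRShapeError):
    """Baseline fitting or correction failed."""


class ExtractionError(EPRShapeError):
    """Classical parameter extraction failed (not a standard derivative line)."""


class TransformError(EPRShapeError):
    """Mapping a spectrum into Benc coordinates failed."""


class QuadratureError(EPRShapeError):
    """Numerical Fourier quadrature of the relaxation function did not converge."""


class IntegrationError(EPRShapeError):
    """The R10 rectangle sum could not be formed."""


class MonteCarloError(EPRShapeError):
    """Monte Carlo error propagation failed."""


class PipelineError(EPRShapeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class MetadataWarning(UserWarning):
    """A filename did not encode acquisition metadata in the expected pattern."""


class DataQualityWarning(UserWarning):
    """The data are usable but violate a soft expectation (index column, x range...)."""
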