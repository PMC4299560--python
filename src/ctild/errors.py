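"""Exception hierarchy shared across the package."""


class CTILDError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CTILDError):
    """Invalid specification or configuration (bad geometry, bad bands, ...)."""


class ValidationError(CTILDError):
    """Invalid user-supplied value (unknown abnormality, negative count, ...)."""


class EmptySegmentationError(CTILDError):
    """Thresholding produced no candidate lung component."""


class UndefinedFractionError(CTILDError):
    """No masked voxel falls inside the total density band."""


class ZeroVarianceError(CTILDError):
    """Histogram is constant; skewness/kurtosis undefined.

    Carries ``mla_hu`` so the mean attenuation is still available.
    """

    def __init__(self, message: str, mla_hu: float | None = None):
        super().__init__(message)
        self.mla_hu = mla_hu


class UndefinedCorrelationError(CTILDError):
    """Zero variance in one of the paired series."""


class DegenerateICCError(CTILDError):
    """No between-subject variance; ICC undefined."""


class CorrelationMatrixError(CTILDError):
    """Target correlation matrix is not repairable to positive semi-definite."""


class MixedSeriesError(CTILDError):
    """A directory holds slices from more than one series."""


class MissingTagError(CTILDError):
    """A required DICOM tag is absent."""


class PipelineError(CTILDError):
    """A pipeline stage failed; message names the stage and cause."""
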