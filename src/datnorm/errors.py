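"""Exception hierarchy for the datnorm pipeline."""


class DatnormError(Exception):
    """Base class for all datnorm errors."""


class InvalidRatioError(DatnormError, ValueError):
    """Striatum:background filling ratio below 1."""


class RasterizationError(DatnormError):
    """Phantom compartments cannot be represented on the requested grid."""


class ConfigurationError(DatnormError):
    """Invalid simulator or pipeline configuration (e.g. unknown condition)."""


class VolumeFormatError(DatnormError):
    """Input image is not a 3-D spatial volume datnorm can quantify."""


class NoSignalError(DatnormError):
    """Volume contains no counts to localize."""


class DegeneratePeakError(DatnormError):
    """No striatal peak stands out from background (e.g. uniform volume)."""


class LateralizationError(DatnormError):
    """Striatal activity could not be found on both sides of the midline."""


class ReferenceRegionError(DatnormError):
    """Reference region empty after brain-masking and striatal exclusion."""


class ZeroReferenceError(DatnormError, ZeroDivisionError):
    """Reference per-voxel count is zero; SBR undefined."""


class DomainError(DatnormError, ValueError):
    """Argument outside its mathematical domain (e.g. R + L <= 0 for AI)."""


class CalibrationQualityError(DatnormError):
    """Fitted calibration curve fails the slope/correlation quality gate."""


class UnusableCurveError(DatnormError):
    """Calibration curve has nonpositive slope and cannot be inverted."""


class MissingCurveError(DatnormError, KeyError):
    """No calibration curve for a (scanner, condition) pair."""

    def __init__(self, scanner: str, condition: str):
        self.scanner = scanner
        self.condition = condition
        super().__init__(f"no calibration curve for scanner={scanner!r}, condition={condition!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class RankError(DatnormError):
    """Design matrix is rank deficient (constant or collinear covariates)."""


class UndefinedIccError(DatnormError):
    """ICC undefined (no variance in either member of the pairs)."""


class DegenerateModelError(DatnormError):
    """Model has zero residual scale; z-scores undefined."""


class SchemaError(DatnormError, ValueError):
    """Tabular artifact does not match its documented column/key dictionary."""


class PipelineStageError(DatnormError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
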