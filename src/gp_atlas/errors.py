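"""Exception hierarchy shared across the package."""


class GPAtlasError(Exception):
    """Base class for all package-specific failures."""


class SeriesRejected(GPAtlasError):
    """An R-wave series cannot be analysed (too few beats, truncated recording)."""


class ConfigurationError(GPAtlasError):
    """A threshold or parameter is out of its valid range."""


class MeshValidationError(GPAtlasError):
    """A surface mesh violates a structural invariant."""


class RegistrationError(GPAtlasError):
    """A registration cannot be fitted (degenerate landmark configuration)."""


class SamplingError(GPAtlasError):
    """A site-sampling request is infeasible on the given surface."""

    def __init__(self, message: str, achievable: int | None = None):
        super().__init__(message)
        self.achievable = achievable


class PipelineStageError(GPAtlasError):
    """A pipeline stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
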