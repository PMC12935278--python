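"""Exception and warning types shared across the package."""


class OctvibError(Exception):
    """Base class for all octvib errors."""


class SingularDirectionsError(OctvibError):
    """Optical axes are (numerically) linearly dependent; the direction
    matrix cannot be inverted."""


class DegenerateGeometryError(OctvibError):
    """Input geometry does not define the requested construction
    (collinear landmarks, empty surfaces, degenerate planes, ...)."""


class EmptyCloudError(DegenerateGeometryError):
    """No surface point survived extraction."""


class UnitError(OctvibError):
    """Data carries the wrong physical units for the operation."""


class InsufficientDataError(OctvibError):
    """Too few samples/pixels to compute the requested statistic."""


class PipelineStageError(OctvibError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class RegistrationWarning(UserWarning):
    """Registration quality below the configured threshold, or degenerate
    cloud geometry (e.g. a single plane leaves in-plane translation
    unobservable)."""


class SaturationWarning(UserWarning):
    """Phase differences exceed the (-pi, pi] linear regime."""


class LowSNRWarning(UserWarning):
    """Signal-to-noise ratio at or below the Rician-bias threshold."""
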