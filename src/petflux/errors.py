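"""Exception hierarchy shared across the package."""


class PetfluxError(Exception):
    """Base class for all package-specific errors."""


class DegenerateModelError(PetfluxError):
    """Kinetic model parameters make the requested quantity undefined."""


class CoverageError(PetfluxError):
    """A curve does not cover the requested time range."""


class InsufficientDataError(PetfluxError):
    """Too few points for the requested fit."""


class DivisionError(PetfluxError):
    """A plasma value of zero makes a normalized coordinate undefined."""


class DomainError(PetfluxError):
    """An input falls outside the operation's mathematical domain."""


class CalibrationError(PetfluxError):
    """Invalid well-counter calibration factor."""


class EmptyRoiError(PetfluxError):
    """Segmentation produced no voxels (seed on background)."""


class GeometryError(PetfluxError):
    """A synthetic object does not fit in the requested grid."""


class SpecError(PetfluxError):
    """Invalid simulation specification."""


class SchemaError(PetfluxError):
    """An input table violates its declared schema."""
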