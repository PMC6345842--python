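"""Exception hierarchy.

Every failure mode surfaced by the library maps onto one of these classes so
that the pipeline can record a stable reason code per (subject, sample,
feature) without string matching.
"""


class RadperturbError(Exception):
    """Base class for all library errors."""


class FormatError(RadperturbError):
    """A file could not be read or parsed as the declared format."""


class GeometryError(RadperturbError):
    """Inconsistent or unusable spatial geometry (slices, planes, grids)."""


class ParameterError(RadperturbError, ValueError):
    """An operator parameter is outside its valid domain."""


class SpecError(RadperturbError, ValueError):
    """An invalid phantom or run specification."""


class DegenerateMaskError(RadperturbError):
    """A processing step left the ROI mask empty (or effectively unusable)."""


class CoverageError(GeometryError):
    """A geometric transform moved the ROI entirely outside the grid."""


class ConfigurationError(RadperturbError, ValueError):
    """A configuration value is inconsistent with the data it is applied to."""
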