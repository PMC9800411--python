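"""Exception hierarchy for hydroform."""


class HydroformError(Exception):
    """Base class for all package errors."""


class MeshFormatError(HydroformError):
    """A surface-model file could not be parsed."""


class MeshGeometryError(HydroformError):
    """Mesh violates a geometric precondition (e.g. not watertight)."""


class DegenerateConfigurationError(HydroformError):
    """Input configuration is degenerate (too few / collinear landmarks)."""


class RegionError(HydroformError):
    """Region definition or transfer failed."""


class StudyError(HydroformError):
    """Study-level failure (no usable specimen pairs, bad config)."""
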