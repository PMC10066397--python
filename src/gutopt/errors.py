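"""Exception types shared across the package."""


class GutOptError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(GutOptError):
    """A phantom or sampling geometry violates its invariants."""


class ParameterError(GutOptError):
    """A parameter is outside its admissible range."""


class EmptyMaskError(GutOptError):
    """Segmentation produced no foreground."""


class InsufficientObjectsError(GutOptError):
    """An operation needs more segmented objects than are available."""


class MetadataError(GutOptError):
    """Required image metadata (voxel size, angles) is missing or inconsistent."""
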