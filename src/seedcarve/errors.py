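"""Exception hierarchy for seedcarve.

All errors raised by the library derive from :class:`SeedCarveError` so
callers (and the CLI) can distinguish configuration problems, segmentation
failures and carving failures by exception class.
"""


class SeedCarveError(Exception):
    """Base class for all seedcarve errors."""


class ConfigError(SeedCarveError):
    """Invalid or missing configuration / calibration input."""


class GeometryError(SeedCarveError):
    """Geometrically invalid camera or scene parameters."""


class ProjectionError(SeedCarveError):
    """A point cannot be projected (degenerate homogeneous coordinate)."""


class EmptyMaskError(SeedCarveError):
    """A silhouette mask is empty; carving would erase the whole volume."""


class EmptyVolumeError(SeedCarveError):
    """Carving produced an empty occupancy grid (segmentation/pose failure)."""


class ToolNotFoundError(SeedCarveError):
    """No foreground component touches the bottom image border."""


class DegenerateToolError(SeedCarveError):
    """The tool silhouette never narrows; no tip can be located."""


class FitFailureError(SeedCarveError):
    """A least-squares fit (sinusoid, tool cone) could not be performed."""


class RenderError(SeedCarveError):
    """Synthetic scene cannot be rendered (object outside the image)."""
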