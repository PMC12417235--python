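"""Exception hierarchy.

Every error carries a short machine-readable ``category`` string that the CLI
echoes into its error record, so scripted callers can branch on failure mode
without parsing messages.
"""


class OdacsError(Exception):
    """Base class for all package errors."""

    category = "error"


class ImageIOError(OdacsError):
    """A volume or mask file could not be read or written."""

    category = "io"


class DimensionalityError(OdacsError):
    """An image does not have exactly three spatial axes."""

    category = "dimensionality"


class GeometryError(OdacsError):
    """Invalid spacing, orientation, plane, or transform."""

    category = "geometry"


class GridMismatchError(GeometryError):
    """Two objects that must share a voxel grid do not."""

    category = "grid_mismatch"


class NoHypoperfusionError(OdacsError):
    """The thresholded Tmax map is empty; the patient has no measurable
    hypoperfused area and is excluded from scoring."""

    category = "no_hypoperfusion"


class DomainError(OdacsError):
    """An argument is outside its mathematical domain."""

    category = "domain"


class ConfigError(OdacsError):
    """A configuration file or value is invalid."""

    category = "config"


class GenerationError(OdacsError):
    """A phantom specification is infeasible."""

    category = "generation"
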