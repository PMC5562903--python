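"""Exception hierarchy shared across the pipeline stages."""


class FlyAssayError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FlyAssayError, ValueError):
    """A simulation or estimation parameter is out of its valid range."""


class UnattainableShiftError(InvalidParameterError):
    """A latent normal shift cannot realise the requested Cliff's delta (|delta| >= 1)."""


class ConfigError(FlyAssayError, ValueError):
    """A scenario configuration document failed validation."""


class GeometryError(FlyAssayError, ValueError):
    """An arena or alcove polygon is degenerate or out of bounds."""


class InsufficientDataError(FlyAssayError, ValueError):
    """Too few observations for the requested computation."""


class MalformedTrajectoryError(FlyAssayError, ValueError):
    """Trajectory timestamps are not strictly increasing or coordinates are not finite."""


class InvalidMeasurementError(FlyAssayError, ValueError):
    """A raw assay reading is physically impossible (e.g. negative climb time)."""


class MalformedReadingError(InvalidMeasurementError):
    """A capillary or respirometry reading is malformed (e.g. negative level drop)."""


class OrderingError(InvalidMeasurementError):
    """Body-composition masses violate wet >= dry >= lean-dry >= 0."""


class DegenerateVarianceError(FlyAssayError, ValueError):
    """Pooled SD is zero while the group means differ; g is undefined."""


class InvalidRecordError(FlyAssayError, ValueError):
    """A digitized summary record is invalid (e.g. non-positive dispersion)."""


class CollisionError(FlyAssayError, ValueError):
    """Two effect estimates claim the same (driver, metric) cell."""
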