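"""Exception hierarchy.

Errors are split so callers (and the CLI exit codes) can distinguish bad
configuration, insufficient or degenerate input data, and numerical failure.
"""


class GrainStereoError(Exception):
    """Base class for all package errors."""


class ConfigError(GrainStereoError):
    """Invalid or missing configuration / parameters."""


class DegenerateGeometryError(GrainStereoError):
    """Geometry too degenerate to solve (parallel rays, point in focal plane...)."""


class SingularGeometryError(DegenerateGeometryError):
    """Singular normal equations (collinear or coincident control points)."""


class ConvergenceError(GrainStereoError):
    """An iterative solver failed to converge within its iteration cap."""


class InsufficientControlError(GrainStereoError):
    """Too few control points detected or supplied."""


class OrderingError(GrainStereoError):
    """Grid ordering of detected control points is ambiguous."""


class SegmentationError(GrainStereoError):
    """Segmentation cannot proceed (constant image, tiny component...)."""


class ProfileError(GrainStereoError):
    """A polar edge profile cannot be built (centroid outside boundary, gaps...)."""


class PackingError(GrainStereoError):
    """Random placement could not fit the requested grains on the board."""
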