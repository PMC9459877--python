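"""Exception hierarchy for the clothgait pipeline.

Every stage raises a subclass of :class:`ClothGaitError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class ClothGaitError(Exception):
    """Base class for all clothgait errors."""


class InvalidParameterError(ClothGaitError, ValueError):
    """A parameter violates its documented domain (non-positive duration, ...)."""


class InsufficientDataError(ClothGaitError):
    """A series is too short for the requested operation."""


class NotStandingError(ClothGaitError):
    """A segment labelled as standing is not quasi-static."""


class DegenerateAxisError(ClothGaitError):
    """Gravity-alignment axis is undefined (mean acceleration antiparallel to z)."""


class InsufficientExcitationError(ClothGaitError):
    """Too little sagittal-plane motion to estimate the anterior direction."""


class InvalidQuaternionError(ClothGaitError):
    """A quaternion series is not unit norm within tolerance."""


class CannotSegmentError(ClothGaitError):
    """Fewer than two mid-swing points: no cycles can be cut."""


class NumericalFailureError(ClothGaitError):
    """An integration produced non-finite output."""


class SynchronizationError(ClothGaitError):
    """Two streams that must share a time base do not."""


class SchemaError(ClothGaitError):
    """A file does not conform to the documented columnar schema."""


class ConfigurationError(ClothGaitError):
    """A session or protocol misses a required ingredient (e.g. a standing segment)."""


class EmptyResultError(ClothGaitError):
    """An operation that must return at least one value has nothing to return."""
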