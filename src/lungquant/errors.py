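"""Exception types shared across the package."""


class LungQuantError(Exception):
    """Base class for package errors."""


class SeedOutOfBoundsError(LungQuantError, IndexError):
    """A voxel seed lies outside the volume grid."""


class DataError(LungQuantError, ValueError):
    """Input data violates a documented precondition (non-finite HU, etc.)."""


class SplitFailedError(LungQuantError):
    """Left/right separation failed and no fallback plane was supplied."""


class TrainingError(LungQuantError, ValueError):
    """A classifier training set violates its preconditions."""


class EmptyHistogramError(LungQuantError, ValueError):
    """An operation requiring counts was given an all-zero histogram."""
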