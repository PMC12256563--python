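"""Exception hierarchy for helixreg.

All domain errors derive from :class:`HelixregError` so callers (and the CLI)
can distinguish validation failures from I/O problems.
"""


class HelixregError(Exception):
    """Base class for all helixreg domain errors."""


class FrameChainError(HelixregError):
    """Transform frames do not chain (``a.frame_from != b.frame_to``)."""


class DegenerateTransformError(HelixregError):
    """Transform matrix is singular or otherwise unusable."""


class ReflectionError(HelixregError):
    """Linear part has non-positive determinant; no rigid projection exists."""


class GeometryError(HelixregError):
    """Phantom geometry is internally inconsistent (e.g. helix too long)."""


class PatternValidationError(HelixregError):
    """No run length up to the number of large fiducials identifies the pattern."""


class FormatError(HelixregError):
    """A volume or transform file failed to parse."""


class UnsupportedGeometryError(HelixregError):
    """Volume carries a non-identity direction matrix."""


class ConfigurationError(HelixregError):
    """Invalid or incomplete configuration for an operation."""


class InsufficientFiducialsError(HelixregError):
    """Fewer large fiducials detected than the correspondence requires."""


class AmbiguousCorrespondenceError(HelixregError):
    """Pattern matching produced a duplicate or near-tied assignment."""


class RankDeficiencyError(HelixregError):
    """Corresponding point sets are coplanar/degenerate for an affine fit."""


class SegmentationError(HelixregError):
    """Treatment-zone segmentation produced an empty region."""


class UndefinedStatisticError(HelixregError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
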