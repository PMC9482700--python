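"""Exception hierarchy for sfproj."""


class SfprojError(Exception):
    """Base class for all sfproj errors."""


class ValidationError(SfprojError):
    """An input failed a numerical validity check (orthonormality, unit norm, ...)."""


class InvalidSequenceError(SfprojError):
    """An Euler axis sequence is malformed (unknown or repeated consecutive labels)."""


class UndefinedAxisError(SfprojError):
    """The rotation axis is undefined (identity rotation)."""


class AmbiguousBoundaryError(SfprojError):
    """The occupied region has no single consistent outer perimeter."""


class InvalidPolygonError(SfprojError):
    """A spherical polygon violates its invariants (too few vertices, antipodal
    neighbours, self-intersection)."""


class IndeterminatePathError(SfprojError):
    """A containment test ray is degenerate (query antipodal to the reference point)."""


class UnanchoredStartError(SfprojError):
    """The start pose of a path query is not near any sampled orientation."""


class FitError(SfprojError):
    """A geometric fit (plane, line, frame) is degenerate or failed to converge."""


class FormatError(SfprojError):
    """A file could not be parsed under any supported representation."""
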