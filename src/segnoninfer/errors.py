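"""Exception hierarchy for segnoninfer.

All package-specific failures derive from :class:`SegEvalError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class SegEvalError(Exception):
    """Base class for all segnoninfer errors."""


class DimensionalityError(SegEvalError):
    """A volume is not 3D after squeezing trailing singleton dimensions."""


class GeometryError(SegEvalError):
    """Voxel spacing is missing, non-positive, or otherwise unusable."""


class GridCompatibilityError(SegEvalError):
    """Two masks do not share the same voxel grid (shape or spacing)."""


class UndefinedDistanceError(SegEvalError):
    """A surface-distance query against an empty surface set."""


class InsufficientDataError(SegEvalError):
    """Too few observations for the requested statistic."""


class GenerationError(SegEvalError):
    """Synthetic-cohort parameters are infeasible on the requested grid."""
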