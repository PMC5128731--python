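"""Exception hierarchy for the segmentation pipeline.

Every stage raises a subclass of :class:`LungTraceError` so callers (and the
slice loop in :mod:`lungtrace.pipeline`) can catch pipeline failures without
masking programming errors.
"""


class LungTraceError(Exception):
    """Base class for all lungtrace errors."""


class InvalidSpec(LungTraceError):
    """A phantom specification violates its geometric invariants."""


class NoBonePixels(LungTraceError):
    """Fewer than two pixels exceed the bone threshold; PCA is undefined."""


class NoForeground(LungTraceError):
    """Binarization produced an empty foreground; no chest is present."""


class StartNotFound(LungTraceError):
    """No diagonal run of lung pixels was found; the slice has no lung."""


class OpenContour(LungTraceError):
    """Border tracing exceeded its step budget without closing."""


class EmptyBand(LungTraceError):
    """The dynamic-programming column band is empty."""


class SplitFailed(LungTraceError):
    """Iterative erosion vanished or hit its budget before splitting."""


class SeparationFailed(LungTraceError):
    """All lung-separation strategies failed on this slice."""


class DegenerateContour(LungTraceError):
    """Contour too short (or step too coarse) for spline resampling."""


class IllConditionedFit(LungTraceError):
    """Least-squares smoothing system is singular."""


class NonConvergence(LungTraceError):
    """Concave correction did not reach perimeter convergence."""


class EmptyReference(LungTraceError):
    """The reference (manual) mask is empty; volume metrics undefined."""


class EmptyMask(LungTraceError):
    """A mask required to be non-empty is empty."""
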