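"""Exception hierarchy.

Every domain failure derives from :class:`FluoroSimError` so callers can
catch the package's errors with a single clause while tests assert the
specific subclass.
"""


class FluoroSimError(Exception):
    """Base class for all domain errors raised by this package."""


# -- geometry ---------------------------------------------------------------

class CollinearPointsError(FluoroSimError):
    """The three source calibration points are (nearly) collinear."""


class SingularTransformError(FluoroSimError):
    """The affine transform's linear part is not invertible."""


# -- vision -----------------------------------------------------------------

class MarkersNotFoundError(FluoroSimError):
    """No sufficiently large component of the marker color was found
    (typically the operator's hand occludes a tracking marker)."""


class AmbiguousMarkerError(FluoroSimError):
    """Strict mode: two or more candidate components tie in area."""


class DegeneratePoseError(FluoroSimError):
    """Proximal and distal marker centroids coincide; no wire direction."""


# -- simulator --------------------------------------------------------------

class SessionClosedError(FluoroSimError):
    """Operation attempted on a closed simulation session."""


class MissingCalibrationError(FluoroSimError):
    """No affine calibration stored for the requested imaging plane."""


class NonMonotoneTimeError(FluoroSimError):
    """Event timestamps must be non-decreasing within a session."""


class IncompleteSessionError(FluoroSimError):
    """Session report requested without a final wire pose in both planes."""


# -- scoring ----------------------------------------------------------------

class NonPositiveDiameterError(FluoroSimError):
    """Wire diameter (true mm or apparent px) must be positive."""


class DegenerateAnchorsError(FluoroSimError):
    """Cut-out curve anchors share a TAD or probability, or imply b <= 0."""


# -- validity ---------------------------------------------------------------

class NegativeCountError(FluoroSimError):
    """DHS case count cannot be negative."""


class EmptyCohortError(FluoroSimError):
    """A cohort has no members."""


class InsufficientGroupsError(FluoroSimError):
    """Kruskal-Wallis needs at least two non-empty groups and total n >= 3."""


class EmptyGroupError(FluoroSimError):
    """Mann-Whitney groups must both be non-empty."""


class BothZeroError(FluoroSimError):
    """Percent difference is undefined when both medians are zero."""


class OutOfScaleError(FluoroSimError):
    """Likert response outside the 1-7 scale."""


# -- fixtures ---------------------------------------------------------------

class MarkerOutOfFrameError(FluoroSimError):
    """Synthetic marker disk would not fit fully inside the frame."""


class GeometryError(FluoroSimError):
    """Inconsistent synthetic anatomy parameters."""


class InvalidSpecError(FluoroSimError):
    """Malformed synthetic cohort specification."""
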