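"""Exception hierarchy for the palpmetrics pipeline.

Every stage raises subclasses of :class:`PalpError` so callers can catch
pipeline failures without also swallowing programming errors.
"""


class PalpError(Exception):
    """Base class for all palpmetrics errors."""


class MissingChannel(PalpError):
    """A required sensor channel is absent from a trial bundle."""


class SchemaError(PalpError):
    """Metadata or configuration fails schema validation."""


class NonMonotoneTime(PalpError):
    """A channel's timestamps are not strictly increasing."""


class EmptyOverlap(PalpError):
    """Channel time ranges do not intersect; no common grid exists."""


class RangeError(PalpError):
    """A GRS score lies outside the 1..7 rating scale."""


class DegenerateInput(PalpError):
    """Too few distinct points to fit a line."""


class IsotropicCloud(PalpError):
    """Point cloud has no dominant direction; axis fit is ill-posed."""


class NotResampled(PalpError):
    """Operation requires a bundle on a uniform common time grid."""


class EmptyWindow(PalpError):
    """Palpation window has non-positive duration."""


class TooFewFrames(PalpError):
    """Not enough valid position frames to estimate velocity."""


class EmptySample(PalpError):
    """A statistical test received an empty sample."""


class ZeroTrials(PalpError):
    """Success probability requested for zero trials."""


class SingleClass(PalpError):
    """Logistic fit requires both outcome classes present."""


class FitFailure(PalpError):
    """Curve fit did not converge or response is unidentifiable."""


class NotSignificant(PalpError):
    """Hill fit requested for a metric whose logistic slope is not significant."""


class DegenerateProfile(PalpError):
    """Synthetic skill profile cannot produce a valid trial."""
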