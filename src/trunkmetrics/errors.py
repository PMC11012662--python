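"""Typed exceptions raised across the package.

Annotation mistakes (a missing landmark, swapped sides, a plumbline that
falls outside the trunk) must surface loudly in batch runs rather than
propagate as NaN, so every failure mode gets its own exception class.
"""


class TrunkMetricsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TrunkMetricsError):
    """A landmark record is structurally incomplete or malformed."""


class LandmarkParseError(TrunkMetricsError):
    """A coordinate could not be parsed as a finite number."""


class SideInversionError(TrunkMetricsError):
    """A patient-left landmark lies at or right of its right counterpart."""


class SideOrderError(TrunkMetricsError):
    """A left/right pair was passed in the wrong horizontal order."""


class DegenerateGeometryError(TrunkMetricsError):
    """Coincident points or a plumbline outside the trunk."""


class UndefinedRatioError(TrunkMetricsError):
    """A left/right area ratio with a zero right-side denominator."""


class IncompleteGridError(TrunkMetricsError):
    """A subject-by-rater ratings grid has missing cells."""
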