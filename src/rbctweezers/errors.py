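"""Exception hierarchy for the tweezers pipeline.

Every stage raises a subclass of :class:`RBCTweezersError`, so callers
(and the CLI, which maps them to exit codes) can distinguish bad
configuration from bad data without string matching.
"""


class RBCTweezersError(Exception):
    """Base class for all package errors."""


class ConfigError(RBCTweezersError):
    """Invalid or inconsistent run configuration."""


class InvalidGeometryError(RBCTweezersError):
    """Non-physical chamber or cell geometry (zero/negative lengths)."""


class InvalidParameterError(RBCTweezersError):
    """Non-physical model parameter (e.g. elasticity <= 0)."""


class UnitError(RBCTweezersError):
    """Unsupported unit or unit pair in a conversion."""


class InsufficientDataError(RBCTweezersError):
    """Too few samples to fit or summarize."""


class DegenerateTrackError(RBCTweezersError):
    """Position track with zero time span or other degeneracy."""


class DegenerateFitError(RBCTweezersError):
    """Regression with no usable stimulus variation (all x zero)."""


class NonPhysicalElasticityError(RBCTweezersError):
    """Elongation decreased with drag velocity: negative fitted stiffness."""


class NoCellFoundError(RBCTweezersError):
    """Segmentation produced an empty mask."""


class AmbiguousSceneError(RBCTweezersError):
    """Multiple comparably sized objects in a frame meant to hold one cell."""


class ScheduleError(RBCTweezersError):
    """Cohort design references a storage day absent from the parameter schedule."""


class ReportError(RBCTweezersError):
    """Report assembly is missing a required summary."""
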