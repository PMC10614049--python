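"""Exception hierarchy for the cfimpact pipeline."""


class CFImpactError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CFImpactError):
    """A scenario or run configuration violates its invariants."""


class GenerationError(CFImpactError):
    """The synthetic landscape generator could not satisfy a constraint
    (e.g. the requested number of disjoint zones does not fit)."""


class ClassificationError(CFImpactError):
    """A land-cover layer contains labels outside the declared class set."""


class SpatialReferenceError(CFImpactError):
    """Raster and vector inputs do not share one grid / planar frame."""


class TemporalRangeError(CFImpactError):
    """A reference year falls outside the panel's calendar span."""


class MissingLayerError(CFImpactError):
    """A required feature layer is empty or absent."""


class PairingError(CFImpactError):
    """A control sample has no matched treated partner where one is required."""


class DesignError(CFImpactError):
    """A regression design is degenerate (too short, rank deficient, or an
    empty event-time window)."""


class CoverageError(CFImpactError):
    """An event time inside the pooled window has no contributing pairs."""


class InsufficientDataError(CFImpactError):
    """Too few observations for the requested statistic."""


class EmptyResultError(CFImpactError):
    """Every matching phase was excluded by the balance filter."""


class SeparationWarning(UserWarning):
    """The propensity model detected (quasi-)complete separation and fell
    back to a ridge-penalized fit."""
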