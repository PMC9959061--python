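"""Exception hierarchy for the staz pipeline.

Every hard failure raised by the package derives from :class:`StazError`,
so callers (and the CLI) can catch one type and exit with a clean message.
"""


class StazError(Exception):
    """Base class for all staz-specific errors."""


class FormatError(StazError):
    """A file could not be read as the format it claims to be."""


class ConfigurationError(StazError):
    """Inconsistent or out-of-range configuration (e.g. a plane index
    that does not exist in the image file)."""


class ShapeMismatchError(StazError):
    """Grids that must share dimensions do not."""


class EmptyRoiError(StazError):
    """A liver mask/ROI contains zero pixels."""


class ConsistencyError(StazError):
    """Derived objects violate an internal invariant (e.g. a droplet
    pixel outside the liver mask)."""


class DegenerateNormalizationError(StazError):
    """The blue normalization channel sums to zero over the liver."""


class DegenerateControlError(StazError):
    """The control-group mean fluorescence ratio is not positive."""


class MissingControlError(StazError):
    """A normalization scope unit (batch) has no control larvae."""


class MissingDataError(StazError):
    """Required measurements are absent (e.g. a larva with no slices)."""


class EmptyGPError(StazError):
    """A GP map has no defined pixels."""


class DegenerateVarianceError(StazError):
    """Within-group variance is zero everywhere; the test statistic is
    undefined."""


class UnbalancedDesignError(StazError):
    """A factorial cell is empty in a two-way layout."""


class PackingError(StazError):
    """Non-overlapping droplet placement failed; the requested density is
    infeasible for the liver geometry."""
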