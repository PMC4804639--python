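"""Exception hierarchy shared across the package."""


class GazeclassError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GazeclassError):
    """A battery/cohort configuration violates the schema; the message names the field."""


class GeometryError(GazeclassError):
    """AoI rectangles are malformed, overlap, or fall outside the screen."""


class GenerationError(GazeclassError):
    """The simulator was asked for something geometrically impossible."""


class IncompleteStreamError(GazeclassError):
    """A gaze stream is missing a stimulus or has the wrong sample count."""


class InsufficientDataError(GazeclassError):
    """A group is empty (or too small) after exclusion for the requested statistic."""


class UndefinedStatisticError(GazeclassError):
    """The requested statistic is undefined (e.g. zero pooled variance)."""


class PanelEmptyError(GazeclassError):
    """No item survived the effect-size screen for the classifier panel."""
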