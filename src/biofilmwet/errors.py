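"""Exception hierarchy shared across the analysis modules."""


class BiofilmWetError(Exception):
    """Base class for all package errors."""


class ParameterError(BiofilmWetError, ValueError):
    """A scalar parameter is outside its admissible range."""


class GeometryError(BiofilmWetError, ValueError):
    """A geometric construction (ROI, cap, dish) does not fit or is degenerate."""


class FitError(BiofilmWetError, ValueError):
    """A regression or circle fit cannot be carried out on the given points."""


class AnalysisError(BiofilmWetError, RuntimeError):
    """A measurement stage failed on otherwise valid inputs (e.g. empty window)."""


class DetectionError(BiofilmWetError, RuntimeError):
    """No target object could be segmented from the image."""


class ConfigError(BiofilmWetError, ValueError):
    """A run configuration or manifest is missing required fields."""


class InputError(BiofilmWetError, ValueError):
    """Input arrays are inconsistent (shape mismatch, empty grid, ...)."""
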