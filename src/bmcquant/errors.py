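"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PipelineError` so callers can
distinguish pipeline failures from programming errors.
"""


class PipelineError(Exception):
    """Base class for all errors raised by bmcquant stages."""


class InputError(PipelineError):
    """Malformed or insufficient input data (shape, length, monotonicity)."""


class ParameterError(PipelineError):
    """A parameter outside its documented domain (e.g. M not in [0, 1])."""


class FormatError(PipelineError):
    """A file that can be opened but does not match the expected layout."""


class SegmentationError(PipelineError):
    """Cell-mask derivation failed (constant or empty image)."""


class NormalizationError(PipelineError):
    """Total-fluorescence normalization impossible (zero-total frame)."""


class AnalysisError(PipelineError):
    """A well-formed input that carries no signal for the requested analysis
    (no bleach detected, no recovery information, missing event)."""


class FitError(AnalysisError):
    """Curve fitting failed to converge; carries diagnostics in args."""
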