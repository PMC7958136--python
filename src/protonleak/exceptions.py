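"""Exception hierarchy for the analysis pipeline."""


class ProtonLeakError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ProtonLeakError, ValueError):
    """An input violates a precondition (negative concentration, zero area, ...)."""


class InsufficientDataError(ProtonLeakError, ValueError):
    """Too few data points to perform the requested fit or resampling."""


class DegenerateFitError(ProtonLeakError, RuntimeError):
    """The data carry no information about the model parameters (e.g. flat response)."""


class NoSignalError(ProtonLeakError, RuntimeError):
    """A correlation curve has no amplitude above baseline; nothing to fit."""


class StageDependencyError(ProtonLeakError, RuntimeError):
    """A pipeline stage was requested without its required inputs or upstream stage."""
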