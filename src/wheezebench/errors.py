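"""Exception hierarchy shared across the pipeline."""


class WheezebenchError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(WheezebenchError):
    """Unreadable or malformed input file (audio, CSV, config)."""


class ParameterError(WheezebenchError):
    """Invalid argument value or inconsistent configuration."""


class DegenerateInputError(WheezebenchError):
    """Input is structurally valid but degenerate for the operation
    (all-zero signal, too few samples/frames/crossings, zero spread)."""


class AnnotationError(WheezebenchError):
    """Annotation references a missing recording or lies out of range."""


class ConvergenceError(WheezebenchError):
    """Iterative fit failed to converge."""
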