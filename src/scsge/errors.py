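"""Exception hierarchy for scsge."""


class ScsgeError(Exception):
    """Base class for all scsge errors."""


class ValidationError(ScsgeError, ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ScsgeError, ValueError):
    """Raised when a file cannot be parsed in its declared format."""


class PipelineError(ScsgeError, RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""
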