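"""Exception types shared across discqc."""


class DiscqcError(Exception):
    """Base class for all discqc errors."""


class ValidationError(DiscqcError, ValueError):
    """Raised when an input value violates a documented contract.

    The message always names the offending field/item so that malformed
    score sheets or expression tables can be fixed by hand.
    """


class PipelineError(DiscqcError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
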