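"""Exception hierarchy shared across the pipeline."""


class HTNetError(Exception):
    """Base class for all htnet errors."""


class FormatError(HTNetError, ValueError):
    """A file does not conform to its declared format (missing column,
    malformed line). The message names the offending column or line."""


class ValidationError(HTNetError, ValueError):
    """Well-formed input violates a semantic invariant (duplicate id,
    out-of-range score, inconsistent fingerprint length)."""


class PipelineError(HTNetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
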