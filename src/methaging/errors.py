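"""Exception hierarchy for the methaging pipeline."""


class MethagingError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MethagingError):
    """A data container violated one of its invariants."""


class QCError(MethagingError):
    """Quality control removed everything, or its inputs were inconsistent."""


class ClockError(MethagingError):
    """A clock definition could not be evaluated on the given beta matrix."""


class StatsError(MethagingError):
    """An inferential operation was called on degenerate input."""


class ConfigError(MethagingError):
    """A pipeline or simulation configuration failed validation."""


class PipelineError(MethagingError):
    """A pipeline stage aborted; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
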