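"""Exception hierarchy shared across the pipeline.

Validation errors map to CLI exit code 2, stage failures to exit code 3.
"""


class DsbscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(DsbscapeError):
    """Invalid input data or configuration."""


class SizingError(ValidationError):
    """A chromosome is too short to host the requested features."""


class UndefinedResultError(DsbscapeError):
    """The requested statistic is undefined for this input (e.g. empty)."""


class StageError(DsbscapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
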