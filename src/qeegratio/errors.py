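"""Exception types shared across the pipeline."""

from __future__ import annotations


class ConfigurationError(ValueError):
    """A configuration field is missing, out of range, or inconsistent.

    The message always names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InsufficientCleanDataError(RuntimeError):
    """Raised when a subject x condition retains less clean data than required.

    The pipeline catches this, logs the exclusion, and drops the
    subject from that condition's analysis; it is not a hard failure.
    """

    def __init__(self, subject_id: str, condition: str,
                 retained_seconds: float, required_seconds: float):
        self.subject_id = subject_id
        self.condition = condition
        self.retained_seconds = retained_seconds
        self.required_seconds = required_seconds
        super().__init__(
            f"subject {subject_id} ({condition}): only {retained_seconds:.1f} s "
            f"of clean data retained, {required_seconds:.1f} s required"
        )


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str | None, cause: BaseException):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        who = f" (subject {subject_id})" if subject_id else ""
        super().__init__(f"stage '{stage}'{who} failed: {cause}")
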